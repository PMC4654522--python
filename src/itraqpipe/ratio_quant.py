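"""Reporter-ion ratio quantitation and threshold differential-expression calls.

Every sample's abundance is expressed as the ratio of its reporter peak area
to the 113 control-channel peak area of its labelling group.  A protein is
called differentially expressed between two samples when the fold ratio
(numerator sample's ratio over denominator sample's) is >= 1.5 or <= 0.67;
no replicate variance model is involved, calls are threshold-only.

Cross-group comparisons (endosperm vs pericarp, e.g. N4/N1) are quotients of
control-channel ratios and are exact only because channel 113 carries the same
reference sample in both groups; this assumption is recorded in output
metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .design import SampleDesign
from .quant_io import ProteinQuantRecord

UP_MIN_DEFAULT = 1.5
DOWN_MAX_DEFAULT = 0.67

#: the seven stage/tissue contrasts reported by the study design
STUDY_COMPARISONS = ("N2/N1", "N3/N2", "N5/N4", "N6/N5", "N4/N1", "N5/N2", "N6/N3")

CALL_UP = "up"
CALL_DOWN = "down"
CALL_UNCHANGED = "unchanged"
CALL_UNDEFINED = "undefined"


@dataclass
class RatioMatrix:
    """Proteins x samples matrix of ratios to the control channel.

    Undefined cells (no record for that protein in the sample's group, zero
    control intensity, or zero reporter intensity) are NaN and never imputed.
    """

    proteins: list[str]
    samples: list[str]
    values: np.ndarray  # float, NaN = masked
    design: SampleDesign
    gene_models: dict[str, str] = field(default_factory=dict)
    n_masked_control: int = 0

    def __post_init__(self) -> None:
        assert self.values.shape == (len(self.proteins), len(self.samples))
        self._pindex = {p: i for i, p in enumerate(self.proteins)}
        self._sindex = {s: j for j, s in enumerate(self.samples)}

    def ratio(self, protein: str, sample: str) -> float:
        return float(self.values[self._pindex[protein], self._sindex[sample]])

    def column(self, sample: str) -> np.ndarray:
        return self.values[:, self._sindex[sample]]

    def mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.proteins, columns=self.samples)

    def log2(self) -> pd.DataFrame:
        with np.errstate(divide="ignore", invalid="ignore"):
            return pd.DataFrame(
                np.log2(self.values), index=self.proteins, columns=self.samples
            )

    def write(self, path: str | Path, metadata: Mapping[str, object] | None = None) -> None:
        from . import __version__

        lines = [f"# itraqpipe ratio matrix v{__version__}"]
        meta = dict(metadata or {})
        meta.setdefault("control_assumption", "channel 113 carries the control sample in every group")
        for k in sorted(meta):
            lines.append(f"# {k}={meta[k]}")
        body = self.dataframe().to_csv(sep="\t", index_label="accession", lineterminator="\n")
        Path(path).write_text("\n".join(lines) + "\n" + body)


def compute_sample_ratios(
    records: Sequence[ProteinQuantRecord], design: SampleDesign
) -> RatioMatrix:
    """Build the ratio matrix over the union of accessions.

    Proteins are ordered lexicographically so that outputs are deterministic
    regardless of input record order.  A zero control intensity masks that
    group's cells for the protein (logged in ``n_masked_control``) but keeps
    the protein's cells from its other group.
    """
    by_key: dict[tuple[str, int], ProteinQuantRecord] = {}
    gene_models: dict[str, str] = {}
    for r in records:
        by_key[(r.accession, r.group_id)] = r
        gene_models.setdefault(r.accession, r.gene_model)

    proteins = sorted({acc for acc, _ in by_key})
    samples = design.sample_ids()
    values = np.full((len(proteins), len(samples)), np.nan)
    n_masked_control = 0

    channel_of = {sid: design.sample_channel(sid) for sid in samples}
    for i, acc in enumerate(proteins):
        for j, sid in enumerate(samples):
            gid, channel = channel_of[sid]
            rec = by_key.get((acc, gid))
            if rec is None:
                continue
            control = rec.channel_intensity[design.control_channel]
            if control <= 0.0:
                n_masked_control += 1
                continue
            reporter = rec.channel_intensity[channel]
            if reporter <= 0.0:
                continue
            values[i, j] = reporter / control

    return RatioMatrix(
        proteins=proteins,
        samples=list(samples),
        values=values,
        design=design,
        gene_models=gene_models,
        n_masked_control=n_masked_control,
    )


@dataclass
class ComparisonResult:
    """Per-protein fold ratios and calls for one sample-vs-sample contrast."""

    numerator: str
    denominator: str
    fold: pd.Series  # indexed by accession, NaN where undefined
    calls: pd.Series  # up / down / unchanged / undefined
    up_min: float = UP_MIN_DEFAULT
    down_max: float = DOWN_MAX_DEFAULT

    @property
    def comparison_id(self) -> str:
        return f"{self.numerator}/{self.denominator}"

    @property
    def counts(self) -> tuple[int, int, int, int]:
        """(n_up, n_down, n_unchanged, n_undefined)."""
        vc = self.calls.value_counts()
        return (
            int(vc.get(CALL_UP, 0)),
            int(vc.get(CALL_DOWN, 0)),
            int(vc.get(CALL_UNCHANGED, 0)),
            int(vc.get(CALL_UNDEFINED, 0)),
        )

    def members(self, call: str) -> frozenset[str]:
        return frozenset(self.calls.index[self.calls == call])


def compare(
    matrix: RatioMatrix,
    numerator: str,
    denominator: str,
    up_min: float = UP_MIN_DEFAULT,
    down_max: float = DOWN_MAX_DEFAULT,
) -> ComparisonResult:
    """Call differential expression for one contrast.

    up iff fold >= up_min; down iff fold <= down_max (both boundaries
    inclusive, on the stored floating value); undefined iff either cell is
    masked.  ``down_max`` is used literally, not as 1/up_min.
    """
    if numerator == denominator:
        raise ValueError("numerator and denominator samples must differ")
    if not (0.0 < down_max < 1.0 < up_min):
        raise ValueError(
            f"thresholds must satisfy 0 < down_max < 1 < up_min, "
            f"got down_max={down_max}, up_min={up_min}"
        )
    for s in (numerator, denominator):
        if s not in matrix.samples:
            raise KeyError(f"sample {s!r} is not a matrix column")

    num = matrix.column(numerator)
    den = matrix.column(denominator)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = num / den
    calls = np.where(
        np.isnan(fold),
        CALL_UNDEFINED,
        np.where(fold >= up_min, CALL_UP, np.where(fold <= down_max, CALL_DOWN, CALL_UNCHANGED)),
    )
    idx = pd.Index(matrix.proteins, name="accession")
    return ComparisonResult(
        numerator=numerator,
        denominator=denominator,
        fold=pd.Series(fold, index=idx, name="fold"),
        calls=pd.Series(calls, index=idx, name="call"),
        up_min=up_min,
        down_max=down_max,
    )


def study_comparisons(
    matrix: RatioMatrix,
    up_min: float = UP_MIN_DEFAULT,
    down_max: float = DOWN_MAX_DEFAULT,
    comparisons: Sequence[str] = STUDY_COMPARISONS,
) -> dict[str, ComparisonResult]:
    """The study's stage-wise and cross-tissue contrasts, each with counts."""
    out: dict[str, ComparisonResult] = {}
    for cid in comparisons:
        num, den = cid.split("/")
        out[cid] = compare(matrix, num, den, up_min=up_min, down_max=down_max)
    return out


def comparison_count_table(results: Mapping[str, ComparisonResult]) -> pd.DataFrame:
    rows = []
    for cid, res in results.items():
        n_up, n_down, n_unchanged, n_undefined = res.counts
        rows.append(
            {
                "comparison": cid,
                "n_up": n_up,
                "n_down": n_down,
                "n_unchanged": n_unchanged,
                "n_undefined": n_undefined,
            }
        )
    return pd.DataFrame(rows)


def write_comparisons(
    results: Mapping[str, ComparisonResult],
    path: str | Path,
    metadata: Mapping[str, object] | None = None,
) -> None:
    from . import __version__

    frames = []
    for cid in results:
        res = results[cid]
        df = pd.DataFrame(
            {
                "comparison": cid,
                "accession": res.fold.index,
                "fold": res.fold.values,
                "call": res.calls.values,
            }
        )
        frames.append(df)
    body = pd.concat(frames, ignore_index=True)
    lines = [f"# itraqpipe comparisons v{__version__}"]
    for k in sorted(metadata or {}):
        lines.append(f"# {k}={metadata[k]}")
    Path(path).write_text(
        "\n".join(lines) + "\n" + body.to_csv(sep="\t", index=False, lineterminator="\n")
    )
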