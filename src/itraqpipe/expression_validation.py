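"""qRT-PCR relative expression (2^-ddCt), replicate QC, and mRNA-protein
concordance.

Each (gene, sample) is measured in three technical replicates; a replicate
triple whose max-min spread strictly exceeds 0.5 Ct is discarded (the
boundary passes).  Relative expression volume is

    dCt  = Ct(gene, sample) - Ct(reference gene, sample)
    ddCt = dCt(sample) - dCt(calibrator sample)
    REV  = 2 ** (-ddCt)

with a housekeeping reference gene (beta-actin in the motivating study) and a
configurable calibrator sample (pericarp at 10 DAP by default).  Concordance
between an mRNA REV profile and the protein ratio profile is scored per
consecutive stage interval within each tissue as agreement of the direction of
change, with a flat band of |log2 change| < log2(1.5) mirroring the protein DE
threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .design import SampleDesign

CT_SPREAD_MAX = 0.5
QC_PASSED = "passed"
QC_DISCARDED = "discarded"

DIR_UP = "up"
DIR_DOWN = "down"
DIR_FLAT = "flat"


class CtError(ValueError):
    pass


def qc_ct(replicates: Sequence[float], max_spread: float = CT_SPREAD_MAX) -> float | None:
    """Mean of three replicate Ct values, or None when the spread disqualifies.

    The triple is discarded when max - min strictly exceeds ``max_spread``;
    a spread of exactly ``max_spread`` passes.
    """
    if len(replicates) != 3:
        raise CtError(f"expected exactly 3 replicate Ct values, got {len(replicates)}")
    values = [float(v) for v in replicates]
    if any(not math.isfinite(v) or v <= 0 for v in values):
        raise CtError(f"Ct values must be finite and > 0, got {values}")
    if max(values) - min(values) > max_spread:
        return None
    return sum(values) / 3.0


@dataclass
class CtTable:
    """Replicate Ct measurements: one row per (gene, sample)."""

    rows: pd.DataFrame  # columns: gene, sample, ct1, ct2, ct3
    reference_gene: str = "actin"
    calibrator_sample: str = "N1"

    def __post_init__(self) -> None:
        required = ("gene", "sample", "ct1", "ct2", "ct3")
        missing = [c for c in required if c not in self.rows.columns]
        if missing:
            raise CtError(f"Ct table missing column(s): {', '.join(missing)}")
        dup = self.rows.duplicated(subset=["gene", "sample"])
        if dup.any():
            raise CtError("duplicate (gene, sample) rows in Ct table")

    def genes(self) -> list[str]:
        return sorted(set(self.rows["gene"]) - {self.reference_gene})

    def samples(self) -> list[str]:
        return sorted(set(self.rows["sample"]))

    def write(self, path: str | Path) -> None:
        self.rows.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_ct_table(
    path: str | Path, reference_gene: str = "actin", calibrator_sample: str = "N1"
) -> CtTable:
    df = pd.read_csv(path, sep="\t", comment="#")
    return CtTable(rows=df, reference_gene=reference_gene, calibrator_sample=calibrator_sample)


@dataclass
class RevResult:
    """Per (gene, sample) dCt, ddCt and relative expression volume."""

    table: pd.DataFrame  # gene, sample, delta_ct, delta_delta_ct, rev, qc_status
    reference_gene: str
    calibrator_sample: str
    max_spread: float = CT_SPREAD_MAX

    def rev_profile(self) -> pd.DataFrame:
        """genes x samples matrix of REV values (NaN where discarded)."""
        return self.table.pivot(index="gene", columns="sample", values="rev")

    def rev_of(self, gene: str, sample: str) -> float:
        sub = self.table[(self.table["gene"] == gene) & (self.table["sample"] == sample)]
        return float(sub["rev"].iloc[0])

    def write(self, path: str | Path) -> None:
        from . import __version__

        lines = [
            f"# itraqpipe relative expression v{__version__}",
            f"# reference_gene={self.reference_gene}",
            f"# calibrator_sample={self.calibrator_sample}",
            f"# replicate_qc=max-min strictly greater than {self.max_spread} Ct discards",
        ]
        Path(path).write_text(
            "\n".join(lines)
            + "\n"
            + self.table.to_csv(sep="\t", index=False, lineterminator="\n")
        )


def rev(ct: CtTable, max_spread: float = CT_SPREAD_MAX) -> RevResult:
    """Compute dCt, ddCt and REV for every (gene, sample) in the table.

    Samples lacking a reference-gene row raise; (gene, sample) cells whose
    replicates fail QC -- or whose gene's calibrator cell fails QC -- are
    marked discarded (REV NaN), never imputed.
    """
    means: dict[tuple[str, str], float | None] = {}
    for row in ct.rows.itertuples(index=False):
        means[(row.gene, row.sample)] = qc_ct(
            (row.ct1, row.ct2, row.ct3), max_spread=max_spread
        )

    samples = ct.samples()
    for s in samples:
        if (ct.reference_gene, s) not in means:
            raise CtError(f"no reference-gene ({ct.reference_gene}) row for sample {s}")
        if means[(ct.reference_gene, s)] is None:
            raise CtError(
                f"reference-gene replicates for sample {s} failed the spread QC"
            )

    out_rows = []
    for gene in ct.genes():
        # dCt per sample, None where the gene's replicates were discarded
        dct: dict[str, float | None] = {}
        for s in samples:
            m = means.get((gene, s))
            dct[s] = None if m is None else m - means[(ct.reference_gene, s)]  # type: ignore[operator]
        calibrator_dct = dct.get(ct.calibrator_sample)
        for s in samples:
            if (gene, s) not in means:
                continue
            if dct[s] is None or calibrator_dct is None:
                out_rows.append(
                    {
                        "gene": gene,
                        "sample": s,
                        "delta_ct": np.nan if dct[s] is None else dct[s],
                        "delta_delta_ct": np.nan,
                        "rev": np.nan,
                        "qc_status": QC_DISCARDED,
                    }
                )
                continue
            ddct = dct[s] - calibrator_dct
            out_rows.append(
                {
                    "gene": gene,
                    "sample": s,
                    "delta_ct": dct[s],
                    "delta_delta_ct": ddct,
                    "rev": 2.0 ** (-ddct),
                    "qc_status": QC_PASSED,
                }
            )
    return RevResult(
        table=pd.DataFrame(
            out_rows,
            columns=["gene", "sample", "delta_ct", "delta_delta_ct", "rev", "qc_status"],
        ),
        reference_gene=ct.reference_gene,
        calibrator_sample=ct.calibrator_sample,
        max_spread=max_spread,
    )


# ---------------------------------------------------------------------- #
# mRNA-protein concordance


def _direction(v_from: float, v_to: float, flat_fold: float) -> str | None:
    if not (np.isfinite(v_from) and np.isfinite(v_to)) or v_from <= 0 or v_to <= 0:
        return None
    change = math.log2(v_to / v_from)
    band = math.log2(flat_fold)
    if change >= band:
        return DIR_UP
    if change <= -band:
        return DIR_DOWN
    return DIR_FLAT


def stage_intervals(design: SampleDesign) -> list[tuple[str, str, str]]:
    """(tissue, from_sample, to_sample) for consecutive stages within each tissue."""
    out = []
    for tissue in sorted({s.tissue for s in design.samples}):
        ordered = design.samples_by_tissue(tissue)
        for a, b in zip(ordered, ordered[1:]):
            out.append((tissue, a.sample_id, b.sample_id))
    return out


@dataclass
class ConcordanceReport:
    intervals: pd.DataFrame  # gene, tissue, from, to, mrna_dir, protein_dir, concordant
    flat_fold: float

    @property
    def fraction_concordant(self) -> float:
        evaluable = self.intervals.dropna(subset=["concordant"])
        if len(evaluable) == 0:
            return float("nan")
        return float(evaluable["concordant"].mean())

    def per_gene(self) -> pd.DataFrame:
        evaluable = self.intervals.dropna(subset=["concordant"])
        g = evaluable.groupby("gene")["concordant"]
        out = g.agg(fraction="mean", n_intervals="size").reset_index()
        out["completely_concordant"] = out["fraction"] == 1.0
        return out

    def completely_concordant_genes(self) -> list[str]:
        pg = self.per_gene()
        return sorted(pg.loc[pg["completely_concordant"], "gene"])


def concordance(
    rev_profile: pd.DataFrame,
    protein_profile: pd.DataFrame,
    design: SampleDesign,
    flat_fold: float = 1.5,
) -> ConcordanceReport:
    """Direction-of-change agreement between mRNA and protein profiles.

    Both inputs are genes/proteins x samples frames sharing index labels and
    the design's sample columns.  For each consecutive stage interval within
    each tissue, the two sides agree when their direction categories (up /
    down / flat within the band) coincide.  Symmetric in its two profile
    arguments and invariant to uniform positive rescaling of either profile.
    """
    missing = [s for s in design.sample_ids() if s not in rev_profile.columns]
    missing += [s for s in design.sample_ids() if s not in protein_profile.columns]
    if missing:
        raise CtError(f"profiles lack design sample column(s): {sorted(set(missing))}")
    genes = [g for g in rev_profile.index if g in set(protein_profile.index)]
    if not genes:
        raise CtError("no shared gene/protein labels between the two profiles")

    rows = []
    for gene in genes:
        for tissue, a, b in stage_intervals(design):
            m = _direction(rev_profile.at[gene, a], rev_profile.at[gene, b], flat_fold)
            p = _direction(
                protein_profile.at[gene, a], protein_profile.at[gene, b], flat_fold
            )
            rows.append(
                {
                    "gene": gene,
                    "tissue": tissue,
                    "from": a,
                    "to": b,
                    "mrna_dir": m,
                    "protein_dir": p,
                    "concordant": (m == p) if (m is not None and p is not None) else None,
                }
            )
    return ConcordanceReport(
        intervals=pd.DataFrame(rows), flat_fold=flat_fold
    )
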