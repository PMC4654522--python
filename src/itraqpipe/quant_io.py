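"""Reading, validating, filtering and writing protein-level quantitation tables.

A quantitation table is one row per identified protein per labelling group,
with peak-area integrals for the four reporter channels and the search-engine
protein/peptide false discovery rates.  All downstream stages consume only the
record type defined here.

Dialect: UTF-8, tab-separated, mandatory header, '.' decimal point, no
thousands separators.  Leading lines starting with '#' are metadata comments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .design import ALL_CHANNELS, SampleDesign

QUANT_COLUMNS = (
    "accession",
    "gene_model",
    "group",
    "i113",
    "i114",
    "i115",
    "i116",
    "protein_fdr",
    "peptide_fdr",
    "n_peptides",
)

DEFAULT_FDR_MAX = 0.05


class QuantTableError(ValueError):
    """Schema or row-level error in a quantitation table."""


@dataclass
class ProteinQuantRecord:
    accession: str
    gene_model: str
    group_id: int
    channel_intensity: dict[str, float]
    protein_fdr: float
    peptide_fdr: float
    n_peptides: int

    def validate(self) -> None:
        for c in ALL_CHANNELS:
            if c not in self.channel_intensity:
                raise QuantTableError(
                    f"{self.accession}: missing intensity for channel {c}"
                )
            v = self.channel_intensity[c]
            if not math.isfinite(v) or v < 0:
                raise QuantTableError(
                    f"{self.accession}: channel {c} intensity must be finite and >= 0, "
                    f"got {v!r}"
                )
        for name, v in (("protein_fdr", self.protein_fdr), ("peptide_fdr", self.peptide_fdr)):
            if not (0.0 <= v <= 1.0):
                raise QuantTableError(
                    f"{self.accession}: {name} must lie in [0, 1], got {v!r}"
                )
        if self.n_peptides < 1:
            raise QuantTableError(
                f"{self.accession}: n_peptides must be a positive integer"
            )

    def is_quantifiable(self, control_channel: str = "113") -> bool:
        return self.channel_intensity.get(control_channel, 0.0) > 0.0


def _records_to_frame(records: Sequence[ProteinQuantRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "accession": r.accession,
                "gene_model": r.gene_model,
                "group": r.group_id,
                "i113": r.channel_intensity["113"],
                "i114": r.channel_intensity["114"],
                "i115": r.channel_intensity["115"],
                "i116": r.channel_intensity["116"],
                "protein_fdr": r.protein_fdr,
                "peptide_fdr": r.peptide_fdr,
                "n_peptides": r.n_peptides,
            }
        )
    return pd.DataFrame(rows, columns=list(QUANT_COLUMNS))


def write_quant_table(
    records: Sequence[ProteinQuantRecord],
    path: str | Path,
    metadata: Mapping[str, object] | None = None,
) -> None:
    """Write records as TSV; metadata goes into '#'-prefixed header comments."""
    from . import __version__

    lines = [f"# itraqpipe quant table v{__version__}"]
    for k in sorted(metadata or {}):
        lines.append(f"# {k}={metadata[k]}")
    body = _records_to_frame(records).to_csv(sep="\t", index=False, lineterminator="\n")
    Path(path).write_text("\n".join(lines) + "\n" + body)


def read_quant_table(
    path: str | Path,
    design: SampleDesign,
    skip_bad_rows: bool = False,
) -> list[ProteinQuantRecord]:
    """Parse a quantitation table into validated records, preserving row order.

    Rows with non-numeric or negative intensities raise a ``QuantTableError``
    citing the 1-based data line number, unless ``skip_bad_rows`` downgrades
    them to dropped rows.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except Exception as e:  # noqa: BLE001 - wrap parser failures uniformly
        raise QuantTableError(f"{path}: cannot parse table: {e}") from e
    missing = [c for c in QUANT_COLUMNS if c not in df.columns]
    if missing:
        raise QuantTableError(f"{path}: missing required column(s): {', '.join(missing)}")

    known_groups = set(design.group_ids())
    records: list[ProteinQuantRecord] = []
    seen_keys: set[tuple[str, int]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            intensities = {}
            for c in ALL_CHANNELS:
                raw = getattr(row, f"i{c}")
                v = float(raw)
                if not math.isfinite(v) or v < 0:
                    raise QuantTableError(
                        f"channel {c} intensity must be finite and >= 0, got {raw!r}"
                    )
                intensities[c] = v
            rec = ProteinQuantRecord(
                accession=str(row.accession),
                gene_model=str(row.gene_model),
                group_id=int(row.group),
                channel_intensity=intensities,
                protein_fdr=float(row.protein_fdr),
                peptide_fdr=float(row.peptide_fdr),
                n_peptides=int(row.n_peptides),
            )
            rec.validate()
            if rec.group_id not in known_groups:
                raise QuantTableError(f"unknown group {rec.group_id}")
            key = (rec.accession, rec.group_id)
            if key in seen_keys:
                raise QuantTableError(f"duplicate (accession, group) key {key}")
            seen_keys.add(key)
        except (ValueError, TypeError) as e:
            msg = f"{path}: line {i}: {e}"
            if skip_bad_rows:
                continue
            raise QuantTableError(msg) from e
        records.append(rec)
    return records


def filter_by_fdr(
    records: Iterable[ProteinQuantRecord],
    protein_fdr_max: float = DEFAULT_FDR_MAX,
    peptide_fdr_max: float = DEFAULT_FDR_MAX,
) -> list[ProteinQuantRecord]:
    """Keep records with protein FDR and peptide FDR both at or below threshold.

    The boundary is inclusive: a record at exactly the threshold passes.
    The input is not modified and relative order is preserved.
    """
    if protein_fdr_max < 0 or peptide_fdr_max < 0:
        raise ValueError("FDR thresholds must be non-negative")
    return [
        r
        for r in records
        if r.protein_fdr <= protein_fdr_max and r.peptide_fdr <= peptide_fdr_max
    ]


@dataclass
class IdentificationSets:
    """Per (tissue, stage) identification sets with the derived count summary.

    A protein counts as identified in a sample when its record in that
    tissue's labelling group has a strictly positive intensity in the sample's
    reporter channel (and a positive control-channel intensity, so that it is
    quantifiable at all).
    """

    sets: dict[tuple[str, int], frozenset[str]]

    def stages(self, tissue: str) -> list[int]:
        return sorted(s for (t, s) in self.sets if t == tissue)

    def tissues(self) -> list[str]:
        return sorted({t for (t, _) in self.sets})

    def get(self, tissue: str, stage_dap: int) -> frozenset[str]:
        return self.sets[(tissue, stage_dap)]

    def sizes(self) -> dict[tuple[str, int], int]:
        return {k: len(v) for k, v in self.sets.items()}

    def tissue_total(self, tissue: str) -> int:
        """Sum of per-stage set sizes (proteins counted once per stage seen)."""
        return sum(len(v) for (t, _), v in self.sets.items() if t == tissue)

    def tissue_union(self, tissue: str) -> frozenset[str]:
        out: set[str] = set()
        for (t, _), v in self.sets.items():
            if t == tissue:
                out |= v
        return frozenset(out)

    def tissue_nonredundant(self, tissue: str) -> int:
        return len(self.tissue_union(tissue))

    def overall_total(self) -> int:
        return sum(len(v) for v in self.sets.values())

    def overall_union(self) -> frozenset[str]:
        out: set[str] = set()
        for v in self.sets.values():
            out |= v
        return frozenset(out)

    def summary(self) -> pd.DataFrame:
        """Table-style accounting: per-stage counts, totals, nonredundant counts."""
        rows = []
        for tissue in self.tissues():
            row: dict[str, object] = {"tissue": tissue}
            for s in self.stages(tissue):
                row[f"{s}DAP"] = len(self.get(tissue, s))
            row["total"] = self.tissue_total(tissue)
            row["nonredundant"] = self.tissue_nonredundant(tissue)
            rows.append(row)
        return pd.DataFrame(rows)


def identification_sets(
    records: Sequence[ProteinQuantRecord], design: SampleDesign
) -> IdentificationSets:
    """Derive per (tissue, stage) identification sets from filtered records."""
    by_group: dict[int, list[ProteinQuantRecord]] = {}
    for r in records:
        by_group.setdefault(r.group_id, []).append(r)

    sets: dict[tuple[str, int], frozenset[str]] = {}
    for sample in design.samples:
        gid, channel = design.sample_channel(sample.sample_id)
        members = {
            r.accession
            for r in by_group.get(gid, [])
            if r.channel_intensity[channel] > 0.0
            and r.is_quantifiable(design.control_channel)
        }
        sets[(sample.tissue, sample.stage_dap)] = frozenset(members)
    return IdentificationSets(sets=sets)
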