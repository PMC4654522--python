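"""Functional-category tallies (GO, COG) and BLAST-based KEGG-orthology intake.

The annotation maps are consumed as prebuilt flat files; the BLAST search that
produced them is upstream of this package.  Percentages are shares of category
*assignments* (a protein annotated with two categories contributes to both
denominators), which is how per-aspect category shares behave in this kind of
descriptive report.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

GO_ASPECTS = ("biological_process", "molecular_function", "cellular_component")

DEFAULT_EVALUE_MAX = 1e-05


class AnnotationError(ValueError):
    pass


@dataclass
class AnnotationMap:
    """accession -> GO (term, aspect) assignments and COG class assignments."""

    go: dict[str, frozenset[tuple[str, str]]] = field(default_factory=dict)
    cog: dict[str, frozenset[str]] = field(default_factory=dict)
    provenance: str = ""


def read_annotation_map(path: str | Path, provenance: str = "") -> AnnotationMap:
    """Read a TSV with columns accession, scheme (go|cog), aspect, category.

    For COG rows the aspect column is ignored (may be empty or '-').
    Unmapped accessions are simply absent.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    required = ("accession", "scheme", "aspect", "category")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise AnnotationError(f"{path}: missing column(s): {', '.join(missing)}")
    go: dict[str, set[tuple[str, str]]] = {}
    cog: dict[str, set[str]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        scheme = row.scheme.lower()
        if scheme == "go":
            if row.aspect not in GO_ASPECTS:
                raise AnnotationError(
                    f"{path}: line {i}: unknown GO aspect {row.aspect!r}"
                )
            go.setdefault(row.accession, set()).add((row.category, row.aspect))
        elif scheme == "cog":
            cog.setdefault(row.accession, set()).add(row.category)
        else:
            raise AnnotationError(f"{path}: line {i}: unknown scheme {row.scheme!r}")
    return AnnotationMap(
        go={k: frozenset(v) for k, v in go.items()},
        cog={k: frozenset(v) for k, v in cog.items()},
        provenance=provenance or str(path),
    )


def tally_categories(
    amap: AnnotationMap, proteins: Iterable[str], scheme: str
) -> list[tuple[str, int, float]]:
    """Ordered (category, count, percentage) tally for one scheme.

    ``scheme`` is ``"cog"`` or ``"go:<aspect>"`` with aspect one of the three
    GO namespaces.  Percentages are 100 * count / total assignments in the
    scheme/aspect, rounded to 2 dp; ordering is by descending count, then
    category name.  An empty protein set gives an empty tally.
    """
    counts: dict[str, int] = {}
    proteins = set(proteins)
    if scheme == "cog":
        for acc in proteins:
            for cat in amap.cog.get(acc, ()):
                counts[cat] = counts.get(cat, 0) + 1
    elif scheme.startswith("go:"):
        aspect = scheme[3:]
        if aspect not in GO_ASPECTS:
            raise AnnotationError(f"unknown GO aspect {aspect!r}")
        for acc in proteins:
            for cat, asp in amap.go.get(acc, ()):
                if asp == aspect:
                    counts[cat] = counts.get(cat, 0) + 1
    else:
        raise AnnotationError(f"unknown scheme {scheme!r}")

    total = sum(counts.values())
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(cat, n, round(100.0 * n / total, 2)) for cat, n in ordered]


def write_tally(
    tally: list[tuple[str, int, float]], path: str | Path, scheme: str
) -> None:
    from . import __version__

    lines = [f"# itraqpipe category tally v{__version__}", f"# scheme={scheme}"]
    df = pd.DataFrame(tally, columns=["category", "count", "percentage"])
    Path(path).write_text(
        "\n".join(lines) + "\n" + df.to_csv(sep="\t", index=False, lineterminator="\n")
    )


# ---------------------------------------------------------------------- #
# BLAST tabular -> KO assignment

_KO_RE = re.compile(r"(K\d{5})")


@dataclass
class KoAssignment:
    """Best KEGG-orthology hit per gene model under an e-value ceiling."""

    assignments: dict[str, tuple[str, float, float]]  # gene_model -> (ko, evalue, bits)
    e_value_max: float = DEFAULT_EVALUE_MAX

    def ko(self, gene_model: str) -> str | None:
        hit = self.assignments.get(gene_model)
        return hit[0] if hit else None

    def __len__(self) -> int:
        return len(self.assignments)


def _extract_ko(subject: str) -> str:
    m = _KO_RE.search(subject)
    return m.group(1) if m else subject


def parse_blast_tabular(
    path: str | Path, e_value_max: float = DEFAULT_EVALUE_MAX
) -> KoAssignment:
    """Parse 12-column BLAST tabular output into best-KO-per-query assignments.

    Hits with e-value above the ceiling are discarded; per query the hit with
    the highest bit score wins, ties broken by lexicographically smallest
    subject id so the result is deterministic.  Subject ids carry the KO
    identifier (a K-number substring, optionally prefixed, else the whole id).
    """
    if e_value_max <= 0:
        raise ValueError("e_value_max must be positive")
    best: dict[str, tuple[float, str, float]] = {}  # query -> (bits, subject, evalue)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise AnnotationError(
                    f"{path}: line {lineno}: expected 12 tab-separated fields, "
                    f"got {len(fields)}"
                )
            query, subject = fields[0], fields[1]
            try:
                evalue = float(fields[10])
                bits = float(fields[11])
            except ValueError as e:
                raise AnnotationError(
                    f"{path}: line {lineno}: non-numeric e-value/bit score"
                ) from e
            if not math.isfinite(evalue) or evalue < 0:
                raise AnnotationError(
                    f"{path}: line {lineno}: invalid e-value {fields[10]!r}"
                )
            if evalue > e_value_max:
                continue
            cur = best.get(query)
            if cur is None or (bits, _neg(subject)) > (cur[0], _neg(cur[1])):
                best[query] = (bits, subject, evalue)
    return KoAssignment(
        assignments={
            q: (_extract_ko(subj), ev, bits) for q, (bits, subj, ev) in best.items()
        },
        e_value_max=e_value_max,
    )


class _neg(str):
    """Reverses lexicographic comparison, so max() prefers the smallest id."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)
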