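"""Synthetic study generator with full ground truth.

Every pipeline stage is testable offline against data whose truth is known by
construction: reporter intensities are 2**(baseline + planted effect + noise)
with i.i.d. normal noise in log2 space (log-normal multiplicative noise, the
natural model when calls are made on multiplicative thresholds), and planted
effects are separated from every decision threshold by a margin, so the true
call under the pipeline's exact thresholds is decidable without simulation
calibration.  The documented margin rule is margin >= 4 * noise_sd.

Generator simplifications relative to real data:

* the 113 control channel is a reference pool carrying every protein at its
  baseline abundance, so ratios are always defined wherever a reporter fires;
* noise is i.i.d. per channel (no channel bias, no isotope impurity bleed);
* FDR failures are planted per protein, never correlated with abundance.

All generators are pure functions of (parameters, seed); accessions are
deterministic ("SYN000001", ...) so outputs diff cleanly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .design import REPORTER_CHANNELS, SampleDesign, default_study_design
from .network_integration import (
    PathwayDB,
    contrast_tissue,
    default_contrasts,
    _contrast_samples,
)
from .annotation import KoAssignment
from .expression_validation import CtTable
from .quant_io import IdentificationSets, ProteinQuantRecord
from .ratio_quant import (
    CALL_DOWN,
    CALL_UNCHANGED,
    CALL_UNDEFINED,
    CALL_UP,
    STUDY_COMPARISONS,
)


class GenerationError(ValueError):
    pass


def _accession(i: int) -> str:
    return f"SYN{i:06d}"


def _gene_model(i: int) -> str:
    return f"GEN{i:06d}"


# ---------------------------------------------------------------------- #
# truth table


@dataclass
class TruthTable:
    """Planted ground truth for one synthetic study."""

    baseline: dict[str, float]  # accession -> log2 abundance
    effects: dict[str, dict[str, float]]  # accession -> sample -> log2 effect
    presence: dict[str, frozenset[str]]  # accession -> samples where present
    de_calls: dict[str, dict[str, str]]  # comparison -> accession -> call
    candidates: frozenset[str]
    candidate_tissues: dict[str, frozenset[str]]
    stage_specific: dict[tuple[str, int], frozenset[str]]
    tissue_specific: dict[str, frozenset[str]]
    fdr_failed: frozenset[str]
    gene_models: dict[str, str]
    seed: int
    params: dict[str, object] = field(default_factory=dict)

    def de_counts(self, comparison: str) -> tuple[int, int]:
        calls = self.de_calls[comparison]
        return (
            sum(1 for c in calls.values() if c == CALL_UP),
            sum(1 for c in calls.values() if c == CALL_DOWN),
        )

    def candidates_for_tissue(self, tissue: str) -> frozenset[str]:
        return frozenset(
            acc for acc in self.candidates if tissue in self.candidate_tissues[acc]
        )


# ---------------------------------------------------------------------- #
# main study generator


def generate_study(
    design: SampleDesign | None = None,
    n_proteins: int = 500,
    de_counts: Mapping[str, tuple[int, int]] | None = None,
    candidate_counts: Mapping[str, int] | None = None,
    stage_specific: Mapping[tuple[str, int], int] | None = None,
    tissue_specific: Mapping[str, int] | None = None,
    noise_sd: float = 0.1,
    margin: float | None = None,
    up_min: float = 1.5,
    down_max: float = 0.67,
    fold_min: float = 5.0,
    candidate_tail_max: float = 1.5,
    fdr_fail_fraction: float = 0.0,
    contrasts: Sequence[str] | None = None,
    seed: int = 0,
) -> tuple[list[ProteinQuantRecord], TruthTable]:
    """Generate a quantitation table plus its ground truth.

    ``de_counts`` plants per-comparison (n_up, n_down) differential proteins
    (one disjoint block per comparison, effect on the numerator sample only);
    ``candidate_counts`` plants high-fold candidates per tissue (keys
    'pericarp', 'endosperm', and 'cross' for candidates visible only in
    cross-tissue contrasts); ``stage_specific``/``tissue_specific`` plant
    identification dropout.  Remaining proteins are null (present everywhere,
    no effect).

    Truth calls are derived from the planted effects under the exact pipeline
    thresholds, so cross-talk between planted blocks (a protein planted for
    one comparison inevitably shifts others that share its sample) is
    accounted for.
    """
    if noise_sd < 0:
        raise GenerationError("noise_sd must be >= 0")
    design = design or default_study_design()
    if margin is None:
        margin = max(4.0 * noise_sd, 1e-6)
    if margin <= 0:
        raise GenerationError("margin must be > 0")
    rng = np.random.default_rng(seed)
    de_counts = dict(de_counts or {})
    candidate_counts = dict(candidate_counts or {})
    stage_specific = dict(stage_specific or {})
    tissue_specific = dict(tissue_specific or {})
    samples = design.sample_ids()
    control = design.control_sample

    de_delta = math.log2(up_min) + margin
    cand_delta = math.log2(fold_min) + margin
    if de_delta >= math.log2(fold_min) - margin:
        raise GenerationError(
            "DE effect would cross the candidate threshold; reduce margin"
        )

    # ---- allocate disjoint protein blocks ----
    cursor = 0

    def take(n: int, what: str) -> list[str]:
        nonlocal cursor
        if cursor + n > n_proteins:
            raise GenerationError(
                f"n_proteins={n_proteins} too small to plant {what} "
                f"(need {cursor + n})"
            )
        out = [_accession(i + 1) for i in range(cursor, cursor + n)]
        cursor += n
        return out

    effects: dict[str, dict[str, float]] = {}
    presence: dict[str, frozenset[str]] = {}
    all_samples = frozenset(samples)

    stage_specific_truth: dict[tuple[str, int], set[str]] = {}
    for (tissue, stage), n in sorted(stage_specific.items()):
        block = take(n, f"stage-specific ({tissue}, {stage})")
        sid = next(
            s.sample_id
            for s in design.samples
            if s.tissue == tissue and s.stage_dap == stage
        )
        for acc in block:
            presence[acc] = frozenset([sid])
        stage_specific_truth[(tissue, stage)] = set(block)

    tissue_specific_truth: dict[str, set[str]] = {}
    for tissue, n in sorted(tissue_specific.items()):
        block = take(n, f"tissue-specific ({tissue})")
        sids = frozenset(s.sample_id for s in design.samples_by_tissue(tissue))
        for acc in block:
            presence[acc] = sids
        tissue_specific_truth[tissue] = set(block)

    for cid, (n_up, n_down) in sorted(de_counts.items()):
        num, _den = cid.split("/")
        block = take(n_up + n_down, f"DE for {cid}")
        for i, acc in enumerate(block):
            sign = 1.0 if i < n_up else -1.0
            effects.setdefault(acc, {})[num] = sign * de_delta

    # candidates: pericarp on its 20 DAP sample, endosperm on its 20 DAP
    # sample, 'cross' split between the two so only cross-tissue pairs trigger
    tissue_20dap = {
        s.tissue: s.sample_id for s in design.samples if s.stage_dap == 20
    }
    for tissue, n in sorted(candidate_counts.items()):
        block = take(n, f"candidates ({tissue})")
        # cross candidates split the effect between the tissues; each half must
        # stay margin-separated below the single-contrast threshold
        cross_tail_max = min(
            candidate_tail_max,
            max(0.0, 2.0 * (math.log2(fold_min) - margin) - cand_delta),
        )
        for i, acc in enumerate(block):
            sign = 1.0 if i % 2 == 0 else -1.0
            if tissue == "cross":
                tail = float(rng.uniform(0.0, cross_tail_max))
                half = (cand_delta + tail) / 2.0
                effects.setdefault(acc, {})[tissue_20dap["pericarp"]] = sign * half
                effects.setdefault(acc, {})[tissue_20dap["endosperm"]] = -sign * half
            else:
                if tissue not in tissue_20dap:
                    raise GenerationError(f"unknown candidate tissue {tissue!r}")
                # fold-change tail beyond the cutoff
                tail = float(rng.uniform(0.0, candidate_tail_max)) if candidate_tail_max else 0.0
                effects.setdefault(acc, {})[tissue_20dap[tissue]] = sign * (
                    cand_delta + tail
                )

    n_null = n_proteins - cursor
    take(n_null, "null block")  # remaining accessions are null

    accessions = [_accession(i + 1) for i in range(n_proteins)]
    for acc in accessions:
        presence.setdefault(acc, all_samples)
        effects.setdefault(acc, {})

    # FDR failures planted among null proteins only, so planted truth sets
    # survive the FDR filter untouched
    n_fail = int(round(fdr_fail_fraction * n_proteins))
    null_block = accessions[n_proteins - n_null :]
    if n_fail > len(null_block):
        raise GenerationError("fdr_fail_fraction exceeds the null block")
    fdr_failed = frozenset(null_block[:n_fail])

    baseline = {acc: float(rng.uniform(14.0, 20.0)) for acc in accessions}

    # ---- emit records ----
    records: list[ProteinQuantRecord] = []
    gene_models = {acc: _gene_model(i + 1) for i, acc in enumerate(accessions)}
    for acc in accessions:
        for g in design.groups:
            intensities: dict[str, float] = {}
            any_reporter = False
            # control channel: reference pool at baseline abundance
            noise_c = float(rng.normal(0.0, noise_sd)) if noise_sd else 0.0
            intensities[design.control_channel] = 2.0 ** (baseline[acc] + noise_c)
            for c in REPORTER_CHANNELS:
                sid = g.channels[c]
                if sid in presence[acc]:
                    noise = float(rng.normal(0.0, noise_sd)) if noise_sd else 0.0
                    eff = effects[acc].get(sid, 0.0)
                    intensities[c] = 2.0 ** (baseline[acc] + eff + noise)
                    any_reporter = True
                else:
                    intensities[c] = 0.0
            if not any_reporter:
                continue
            if acc in fdr_failed:
                pf = float(rng.uniform(0.051, 0.2))
                qf = float(rng.uniform(0.051, 0.2))
            else:
                pf = float(rng.uniform(0.0, 0.05))
                qf = float(rng.uniform(0.0, 0.05))
            records.append(
                ProteinQuantRecord(
                    accession=acc,
                    gene_model=gene_models[acc],
                    group_id=g.group_id,
                    channel_intensity=intensities,
                    protein_fdr=pf,
                    peptide_fdr=qf,
                    n_peptides=int(rng.integers(1, 21)),
                )
            )

    # ---- derive truth calls from planted effects ----
    surviving = [acc for acc in accessions if acc not in fdr_failed]

    de_calls: dict[str, dict[str, str]] = {}
    for cid in STUDY_COMPARISONS:
        num, den = cid.split("/")
        calls: dict[str, str] = {}
        for acc in surviving:
            if num not in presence[acc] or den not in presence[acc]:
                calls[acc] = CALL_UNDEFINED
                continue
            delta = effects[acc].get(num, 0.0) - effects[acc].get(den, 0.0)
            fold = 2.0 ** delta
            if fold >= up_min:
                calls[acc] = CALL_UP
            elif fold <= down_max:
                calls[acc] = CALL_DOWN
            else:
                calls[acc] = CALL_UNCHANGED
        de_calls[cid] = calls

    contrasts = tuple(contrasts or default_contrasts(design))
    cand_threshold = math.log2(fold_min)
    candidates: set[str] = set()
    candidate_tissues: dict[str, frozenset[str]] = {}
    for acc in surviving:
        tissues: set[str] = set()
        hit = False
        for contrast in contrasts:
            a, b = _contrast_samples(contrast, control)
            if a not in presence[acc] or b not in presence[acc]:
                continue
            delta = abs(effects[acc].get(a, 0.0) - effects[acc].get(b, 0.0))
            if delta >= cand_threshold:
                hit = True
                t = contrast_tissue(contrast, design)
                if t is not None:
                    tissues.add(t)
        if hit:
            candidates.add(acc)
            candidate_tissues[acc] = frozenset(tissues)

    truth = TruthTable(
        baseline=baseline,
        effects=effects,
        presence=presence,
        de_calls=de_calls,
        candidates=frozenset(candidates),
        candidate_tissues=candidate_tissues,
        stage_specific={k: frozenset(v) for k, v in stage_specific_truth.items()},
        tissue_specific={k: frozenset(v) for k, v in tissue_specific_truth.items()},
        fdr_failed=fdr_failed,
        gene_models=gene_models,
        seed=seed,
        params={
            "n_proteins": n_proteins,
            "noise_sd": noise_sd,
            "margin": margin,
            "up_min": up_min,
            "fold_min": fold_min,
            "fdr_fail_fraction": fdr_fail_fraction,
        },
    )
    return records, truth


# ---------------------------------------------------------------------- #
# pathway database generator


def generate_pathway_db(
    n_pathways: int = 5,
    n_kos: int = 20,
    edge_density: float = 0.2,
    n_compounds: int = 10,
    seed: int = 0,
) -> PathwayDB:
    """Random KO/pathway/compound reference satisfying the PathwayDB invariants."""
    if n_pathways < 1 or n_kos < 1:
        raise GenerationError("n_pathways and n_kos must be positive")
    if not (0.0 <= edge_density <= 1.0):
        raise GenerationError("edge_density must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    kos = [f"K{i + 1:05d}" for i in range(n_kos)]
    pathways = [f"path:ko{i + 1:05d}" for i in range(n_pathways)]
    compounds = [f"C{i + 1:05d}" for i in range(n_compounds)]

    ko_pathway: dict[str, frozenset[str]] = {}
    for k in kos:
        n_member = int(rng.integers(1, min(3, n_pathways) + 1))
        member = rng.choice(n_pathways, size=n_member, replace=False)
        ko_pathway[k] = frozenset(pathways[i] for i in sorted(member))

    edges: set[frozenset[str]] = set()
    for i in range(n_kos):
        for j in range(i + 1, n_kos):
            if rng.random() < edge_density:
                edges.add(frozenset((kos[i], kos[j])))

    ko_compounds: dict[str, frozenset[str]] = {}
    if n_compounds:
        for k in kos:
            n_c = int(rng.integers(0, 3))
            if n_c:
                chosen = rng.choice(n_compounds, size=min(n_c, n_compounds), replace=False)
                ko_compounds[k] = frozenset(compounds[i] for i in sorted(chosen))

    db = PathwayDB(
        ko_pathway=ko_pathway,
        pathway_desc={p: f"synthetic pathway {p.split(':')[1]}" for p in pathways},
        ko_edges=frozenset(edges),
        ko_compounds=ko_compounds,
    )
    db.validate()
    return db


def generate_ko_assignment(
    gene_models: Sequence[str],
    db: PathwayDB,
    seed: int = 0,
    e_value_max: float = 1e-05,
) -> KoAssignment:
    """Assign each gene model a random KO from the reference (deterministic)."""
    rng = np.random.default_rng(seed)
    kos = sorted(db.declared_kos())
    if not kos:
        raise GenerationError("pathway db declares no KOs")
    assignments = {}
    for gm in sorted(gene_models):
        k = kos[int(rng.integers(0, len(kos)))]
        evalue = float(10.0 ** rng.uniform(-30, math.log10(e_value_max)))
        bits = float(rng.uniform(80, 500))
        assignments[gm] = (k, evalue, bits)
    return KoAssignment(assignments=assignments, e_value_max=e_value_max)


def write_blast_tabular(
    assignment: KoAssignment,
    path: str | Path,
    n_decoys_per_query: int = 2,
    seed: int = 0,
) -> None:
    """Write outfmt-6-style rows whose best-hit parse reproduces ``assignment``.

    Decoy hits either exceed the e-value ceiling or score below the planted
    best hit, so ``parse_blast_tabular`` recovers the assignment exactly.
    """
    rng = np.random.default_rng(seed)
    lines = []
    for gm in sorted(assignment.assignments):
        ko, evalue, bits = assignment.assignments[gm]
        lines.append(
            f"{gm}\tko:{ko}\t95.0\t200\t5\t0\t1\t200\t1\t200\t{evalue:.3e}\t{bits:.1f}"
        )
        for _ in range(n_decoys_per_query):
            if rng.random() < 0.5:
                # fails the e-value ceiling
                ev = float(10.0 ** rng.uniform(math.log10(assignment.e_value_max) + 0.5, 2))
                b = float(rng.uniform(80, 500))
            else:
                # passes the ceiling but scores below the winner
                ev = float(10.0 ** rng.uniform(-30, math.log10(assignment.e_value_max)))
                b = max(10.0, bits - float(rng.uniform(1.0, 50.0)))
            decoy_ko = f"K{int(rng.integers(90000, 99999)):05d}"
            lines.append(
                f"{gm}\tko:{decoy_ko}\t80.0\t180\t20\t2\t1\t180\t1\t180\t{ev:.3e}\t{b:.1f}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------- #
# exact-count identification fixtures


def venn_cells_from_margins(
    stages: Sequence[int],
    stage_totals: Sequence[int],
    all_three: int,
    singles: Sequence[int],
) -> dict[tuple[int, ...], int]:
    """Solve the three pairwise-only Venn cells from printed marginal counts.

    Given per-stage totals, the all-three cell, and the three only-this-stage
    cells, the pairwise cells are uniquely determined; an infeasible spec
    (negative or non-integer cell) raises before any generation.
    """
    if len(stages) != 3 or len(stage_totals) != 3 or len(singles) != 3:
        raise GenerationError("need exactly three stages/totals/singles")
    s1, s2, s3 = stages
    r1, r2, r3 = (
        t - o - all_three for t, o in zip(stage_totals, singles)
    )  # r1 = ab+ac etc.
    if min(r1, r2, r3) < 0:
        raise GenerationError("infeasible Venn spec: margins below fixed cells")
    total2 = r1 + r2 + r3
    if total2 % 2:
        raise GenerationError("infeasible Venn spec: pairwise cells not integral")
    tot = total2 // 2
    ab, ac, bc = tot - r3, tot - r2, tot - r1
    if min(ab, ac, bc) < 0:
        raise GenerationError("infeasible Venn spec: negative pairwise cell")
    return {
        (s1,): singles[0],
        (s2,): singles[1],
        (s3,): singles[2],
        tuple(sorted((s1, s2))): ab,
        tuple(sorted((s1, s3))): ac,
        tuple(sorted((s2, s3))): bc,
        tuple(sorted((s1, s2, s3))): all_three,
    }


def generate_counts_fixture(
    venn_specs: Mapping[str, Mapping[tuple[int, ...], int]],
    shared_between_tissues: int | None = None,
) -> IdentificationSets:
    """Build identification sets whose Venn decomposition equals the spec exactly.

    ``venn_specs`` maps tissue -> {stage-tuple cell: count}.  When
    ``shared_between_tissues`` is given, that many accessions are common to
    the two tissue unions (taken deterministically from each union in sorted
    order); otherwise tissue universes are disjoint.
    """
    sets: dict[tuple[str, int], set[str]] = {}
    unions: dict[str, list[str]] = {}
    for tissue in sorted(venn_specs):
        spec = venn_specs[tissue]
        for cell, n in spec.items():
            if n < 0:
                raise GenerationError(f"negative cell count {cell}: {n}")
        stages = sorted({s for cell in spec for s in cell})
        for s in stages:
            sets.setdefault((tissue, s), set())
        counter = 0
        union: list[str] = []
        for cell in sorted(spec):
            for _ in range(spec[cell]):
                counter += 1
                acc = f"{tissue[:4].upper()}{counter:06d}"
                union.append(acc)
                for s in cell:
                    sets[(tissue, s)].add(acc)
        unions[tissue] = sorted(union)

    if shared_between_tissues:
        tissues = sorted(venn_specs)
        if len(tissues) != 2:
            raise GenerationError("cross-tissue sharing needs exactly two tissues")
        t1, t2 = tissues
        n = shared_between_tissues
        if n > min(len(unions[t1]), len(unions[t2])):
            raise GenerationError(
                "shared_between_tissues exceeds a tissue union size"
            )
        rename = dict(zip(unions[t2][:n], unions[t1][:n]))
        for (tissue, s), members in sets.items():
            if tissue == t2:
                sets[(tissue, s)] = {rename.get(a, a) for a in members}

    return IdentificationSets(
        sets={k: frozenset(v) for k, v in sets.items()}
    )


# ---------------------------------------------------------------------- #
# Ct tables from planted REV profiles


def generate_validation_profiles(
    protein_profile: pd.DataFrame,
    design: SampleDesign,
    concordant_fraction: float = 1.0,
    flat_fold: float = 1.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Planted mRNA REV profiles with a controlled concordant-interval fraction.

    Returns (rev_profiles, truth) where truth has one row per (gene, interval)
    with the planted concordance flag.  The REV profile is built interval by
    interval: a concordant interval repeats the protein's direction category
    (up x2, down x0.5, flat x1), a discordant one picks a different category.
    """
    from .expression_validation import _direction, stage_intervals

    if not (0.0 <= concordant_fraction <= 1.0):
        raise GenerationError("concordant_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    factor = {"up": 2.0, "down": 0.5, "flat": 1.0}
    intervals = stage_intervals(design)
    first_sample = {t: design.samples_by_tissue(t)[0].sample_id for t in
                    {s.tissue for s in design.samples}}

    rev_rows: dict[str, dict[str, float]] = {}
    truth_rows = []
    for gene in protein_profile.index:
        values: dict[str, float] = {}
        for t, sid in first_sample.items():
            values[sid] = 1.0
        for tissue, a, b in intervals:
            p_dir = _direction(
                float(protein_profile.at[gene, a]),
                float(protein_profile.at[gene, b]),
                flat_fold,
            )
            if p_dir is None:
                raise GenerationError(
                    f"protein profile for {gene} is not fully observed"
                )
            concordant = bool(rng.random() < concordant_fraction)
            if concordant:
                m_dir = p_dir
            else:
                m_dir = str(rng.choice(sorted(set(factor) - {p_dir})))
            values[b] = values[a] * factor[m_dir]
            truth_rows.append(
                {
                    "gene": gene,
                    "tissue": tissue,
                    "from": a,
                    "to": b,
                    "planted_concordant": concordant,
                }
            )
        rev_rows[gene] = values

    rev_profiles = pd.DataFrame.from_dict(rev_rows, orient="index")
    rev_profiles = rev_profiles[design.sample_ids()]
    rev_profiles.index.name = "gene"
    return rev_profiles, pd.DataFrame(truth_rows)


def generate_demo_inputs(
    out_dir: str | Path,
    seed: int = 0,
    n_proteins: int = 300,
    noise_sd: float = 0.1,
) -> dict[str, str]:
    """Write a complete synthetic study in pipeline input formats.

    Produces a design, quant table, annotation map, BLAST tabular, pathway db
    flat files, and a Ct table; returns the path map expected by RunConfig.
    Deterministic for a fixed (seed, parameters) pair.
    """
    import pandas as pd

    from .quant_io import write_quant_table
    from .network_integration import write_pathway_db

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = default_study_design()
    design.write(out / "design.yaml")

    records, truth = generate_study(
        design,
        n_proteins=n_proteins,
        de_counts={"N2/N1": (15, 20), "N5/N4": (20, 15)},
        candidate_counts={"pericarp": 4, "endosperm": 10, "cross": 3},
        stage_specific={("pericarp", 20): 5},
        tissue_specific={"endosperm": 6},
        noise_sd=noise_sd,
        seed=seed,
    )
    write_quant_table(records, out / "quant.tsv", {"seed": seed})

    db = generate_pathway_db(n_pathways=6, n_kos=25, edge_density=0.2,
                             n_compounds=8, seed=seed + 1)
    db_paths = write_pathway_db(db, out / "db")
    ko = generate_ko_assignment(
        sorted(truth.gene_models.values()), db, seed=seed + 2
    )
    write_blast_tabular(ko, out / "blast.tsv", seed=seed + 3)

    # annotation map over all accessions, a few flat categories per scheme
    rng = np.random.default_rng(seed + 4)
    go_cats = ["metabolic process", "cellular process", "stimulus response"]
    mf_cats = ["binding", "catalytic activity"]
    cog_cats = ["E", "J", "O", "G"]
    lines = ["accession\tscheme\taspect\tcategory"]
    for acc in sorted(truth.baseline):
        lines.append(
            f"{acc}\tgo\tbiological_process\t{go_cats[int(rng.integers(0, len(go_cats)))]}"
        )
        lines.append(
            f"{acc}\tgo\tmolecular_function\t{mf_cats[int(rng.integers(0, len(mf_cats)))]}"
        )
        lines.append(f"{acc}\tcog\t-\t{cog_cats[int(rng.integers(0, len(cog_cats)))]}")
    (out / "annotation.tsv").write_text("\n".join(lines) + "\n")

    # Ct table for a handful of validation genes named after study proteins
    genes = sorted(truth.baseline)[:8]
    profile = pd.DataFrame(
        2.0 ** rng.normal(0, 1.2, size=(len(genes), 6)),
        index=genes,
        columns=design.sample_ids(),
    )
    profile["N1"] = 1.0
    ct = generate_ct_tables(profile, design, seed=seed + 5)
    ct.write(out / "ct.tsv")

    return {
        "design": str(out / "design.yaml"),
        "quant_table": str(out / "quant.tsv"),
        "annotation_map": str(out / "annotation.tsv"),
        "blast_tabular": str(out / "blast.tsv"),
        "ko_pathway": str(db_paths["ko_pathway"]),
        "ko_edges": str(db_paths["ko_edges"]),
        "ko_compound": str(db_paths["ko_compound"]),
        "pathway_desc": str(db_paths["pathway_desc"]),
        "ct_table": str(out / "ct.tsv"),
    }


def generate_ct_tables(
    rev_profiles: pd.DataFrame,
    design: SampleDesign | None = None,
    reference_gene: str = "actin",
    calibrator_sample: str = "N1",
    base_ct: float = 24.0,
    reference_ct: float = 16.0,
    jitter: float = 0.15,
    discard_cells: Iterable[tuple[str, str]] = (),
    seed: int = 0,
) -> CtTable:
    """Invert planted REV profiles into replicate Ct tables.

    Ct(gene, sample) = base_ct - log2(REV_sample / REV_calibrator), with the
    reference gene flat at ``reference_ct``; replicate triples are symmetric
    (m-d, m, m+d) so their mean is exact and downstream REV recovery is
    limited only by float arithmetic.  Cells listed in ``discard_cells`` get a
    spread of 0.62 Ct, strictly beyond the 0.5-Ct QC bound.
    """
    design = design or default_study_design()
    if calibrator_sample not in rev_profiles.columns:
        raise GenerationError(f"profiles lack calibrator column {calibrator_sample}")
    rng = np.random.default_rng(seed)
    discard = set(discard_cells)
    rows = []
    samples = [s for s in design.sample_ids() if s in rev_profiles.columns]
    for s in samples:
        rows.append(
            {"gene": reference_gene, "sample": s, "ct1": reference_ct,
             "ct2": reference_ct, "ct3": reference_ct}
        )
    for gene in rev_profiles.index:
        cal = float(rev_profiles.at[gene, calibrator_sample])
        if not (cal > 0):
            raise GenerationError(f"calibrator REV for {gene} must be > 0")
        for s in samples:
            v = float(rev_profiles.at[gene, s])
            if not (v > 0):
                raise GenerationError(f"REV for ({gene}, {s}) must be > 0")
            m = base_ct - math.log2(v / cal)
            if (gene, s) in discard:
                d = 0.31
            else:
                d = float(jitter * rng.uniform(0.2, 0.8))
            rows.append(
                {"gene": gene, "sample": s, "ct1": m - d, "ct2": m, "ct3": m + d}
            )
    return CtTable(
        rows=pd.DataFrame(rows, columns=["gene", "sample", "ct1", "ct2", "ct3"]),
        reference_gene=reference_gene,
        calibrator_sample=calibrator_sample,
    )
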