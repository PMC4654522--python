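import numpy as np
import pytest

from itraqpipe.annotation import (
    AnnotationError,
    AnnotationMap,
    parse_blast_tabular,
    read_annotation_map,
    tally_categories,
)


def blast_row(query, subject, evalue, bits):
    return f"{query}\t{subject}\t90.0\t100\t5\t0\t1\t100\t1\t100\t{evalue}\t{bits}"


class TestParseBlastTabular:
    def test_evalue_ceiling_excludes_weak_hits(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(
            "\n".join(
                [
                    blast_row("g1", "ko:K00001", "1e-06", 100.0),
                    blast_row("g1", "ko:K00002", "1e-03", 500.0),  # better bits, fails e-value
                ]
            )
            + "\n"
        )
        ko = parse_blast_tabular(path)
        assert ko.ko("g1") == "K00001"

    def test_no_passing_hits_means_absent(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(blast_row("g1", "ko:K00001", "1e-02", 100.0) + "\n")
        ko = parse_blast_tabular(path)
        assert ko.ko("g1") is None
        assert len(ko) == 0

    def test_ties_break_to_smallest_subject(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(
            "\n".join(
                [
                    blast_row("g1", "ko:K00009", "1e-08", 200.0),
                    blast_row("g1", "ko:K00002", "1e-08", 200.0),
                ]
            )
            + "\n"
        )
        assert parse_blast_tabular(path).ko("g1") == "K00002"

    def test_malformed_rows_cite_line(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("g1\tko:K00001\tonly-three-fields\n")
        with pytest.raises(AnnotationError, match="line 1"):
            parse_blast_tabular(path)
        path.write_text(blast_row("g1", "ko:K1", "not-a-number", 10.0) + "\n")
        with pytest.raises(AnnotationError, match="non-numeric"):
            parse_blast_tabular(path)

    def test_best_hit_matches_per_query_scan(self, tmp_path):
        rng = np.random.default_rng(21)
        lines, best = [], {}
        for q in range(100):
            query = f"g{q:03d}"
            for h in range(int(rng.integers(1, 6))):
                ko = f"ko:K{int(rng.integers(1, 500)):05d}"
                ev = float(10.0 ** rng.uniform(-30, 0))
                bits = float(rng.integers(50, 500))
                lines.append(blast_row(query, ko, f"{ev:.3e}", bits))
                if float(f"{ev:.3e}") <= 1e-05:
                    key = (bits, tuple(-ord(c) for c in ko))
                    if query not in best or key > best[query][0]:
                        best[query] = (key, ko.split(":")[1])
        path = tmp_path / "hits.tsv"
        path.write_text("\n".join(lines) + "\n")
        parsed = parse_blast_tabular(path)
        assert len(parsed) == len(best)
        for q, (_, ko) in best.items():
            assert parsed.ko(q) == ko


class TestTallyCategories:
    def amap(self):
        return AnnotationMap(
            go={
                "P1": frozenset({("metabolic process", "biological_process")}),
                "P2": frozenset(
                    {
                        ("metabolic process", "biological_process"),
                        ("binding", "molecular_function"),
                    }
                ),
                "P3": frozenset(
                    {
                        ("cellular process", "biological_process"),
                        ("metabolic process", "biological_process"),
                    }
                ),
            },
            cog={"P1": frozenset({"E"}), "P2": frozenset({"E", "J"})},
        )

    def test_single_protein_single_category(self):
        tally = tally_categories(self.amap(), {"P1"}, "go:biological_process")
        assert tally == [("metabolic process", 1, 100.0)]

    def test_hand_counted_shares(self):
        # bp assignments: metabolic x3, cellular x1 -> 75% / 25%
        tally = tally_categories(self.amap(), {"P1", "P2", "P3"}, "go:biological_process")
        assert tally == [("metabolic process", 3, 75.0), ("cellular process", 1, 25.0)]

    def test_empty_protein_set_is_empty_tally(self):
        assert tally_categories(self.amap(), set(), "cog") == []

    def test_percentages_sum_to_100(self):
        for scheme in ("go:biological_process", "go:molecular_function", "cog"):
            tally = tally_categories(self.amap(), {"P1", "P2", "P3"}, scheme)
            if tally:
                assert sum(p for _, _, p in tally) == pytest.approx(100.0, abs=0.05)

    def test_tally_is_monotone_in_proteins(self):
        small = dict(tally_to_map(tally_categories(self.amap(), {"P1"}, "cog")))
        big = dict(tally_to_map(tally_categories(self.amap(), {"P1", "P2"}, "cog")))
        for cat, n in small.items():
            assert big.get(cat, 0) >= n

    def test_unknown_scheme_rejected(self):
        with pytest.raises(AnnotationError):
            tally_categories(self.amap(), {"P1"}, "go:pathway")

    def test_planted_proportions_recovered(self):
        rng = np.random.default_rng(13)
        go = {}
        planted = {"catA": 0.5, "catB": 0.3, "catC": 0.2}
        cats = list(planted)
        probs = list(planted.values())
        for i in range(2000):
            cat = cats[int(rng.choice(3, p=probs))]
            go[f"P{i}"] = frozenset({(cat, "biological_process")})
        amap = AnnotationMap(go=go)
        tally = tally_categories(amap, set(go), "go:biological_process")
        for cat, _, pct in tally:
            assert pct == pytest.approx(100 * planted[cat], abs=3.0)


def tally_to_map(tally):
    return [(cat, n) for cat, n, _ in tally]


def test_annotation_map_round_trip(tmp_path):
    path = tmp_path / "ann.tsv"
    path.write_text(
        "accession\tscheme\taspect\tcategory\n"
        "P1\tgo\tbiological_process\tmetabolic process\n"
        "P1\tcog\t-\tE\n"
        "P2\tgo\tmolecular_function\tbinding\n"
    )
    amap = read_annotation_map(path)
    assert amap.go["P1"] == frozenset({("metabolic process", "biological_process")})
    assert amap.cog["P1"] == frozenset({"E"})
    assert "P3" not in amap.go  # unmapped accessions absent, not empty


def test_annotation_map_rejects_bad_aspect(tmp_path):
    path = tmp_path / "ann.tsv"
    path.write_text("accession\tscheme\taspect\tcategory\nP1\tgo\tpathway\tx\n")
    with pytest.raises(AnnotationError, match="aspect"):
        read_annotation_map(path)
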