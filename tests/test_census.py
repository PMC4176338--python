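import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ppstall import (
    MotifCensus,
    ProteinRecord,
    ProteomeSpec,
    census,
    composition,
    enrichment_table,
    expected_count,
    find_proline_runs,
    gen_proteome,
    shuffle_null,
)
from ppstall.census import TERMINUS
from ppstall.io import STANDARD_RESIDUES


def brute_force_run_counts(seq: str, min_run: int = 3) -> dict[str, int]:
    """Independent character-scan oracle: counts of maximal P-runs keyed by
    the residue preceding each run (TERMINUS for runs at position 0)."""
    counts: dict[str, int] = {}
    i = 0
    while i < len(seq):
        if seq[i] == "P":
            j = i
            while j < len(seq) and seq[j] == "P":
                j += 1
            if j - i >= min_run:
                key = seq[i - 1] if i > 0 else TERMINUS
                counts[key] = counts.get(key, 0) + 1
            i = j
        else:
            i += 1
    return counts


class TestFindProlineRuns:
    def test_no_prolines(self):
        assert find_proline_runs(ProteinRecord(id="a", sequence="MKT")) == []

    def test_internal_run_with_context(self):
        (run,) = find_proline_runs(ProteinRecord(id="a", sequence="ATPPPK"))
        assert (run.start, run.length) == (2, 3)
        assert run.x_residue == "T"
        assert run.z_residue == "K"
        assert run.upstream == "AT"

    def test_n_terminal_run_has_terminus_marker(self):
        (run,) = find_proline_runs(ProteinRecord(id="a", sequence="PPPPA"))
        assert (run.start, run.length) == (0, 4)
        assert run.x_residue == TERMINUS
        assert run.z_residue == "A"
        assert run.upstream == ""

    def test_c_terminal_run(self):
        (run,) = find_proline_runs(ProteinRecord(id="a", sequence="MKTPPP"))
        assert run.z_residue == TERMINUS
        assert run.upstream == "MKT"

    def test_short_runs_ignored_and_min_run_2(self):
        rec = ProteinRecord(id="a", sequence="APPAK")
        assert find_proline_runs(rec, min_run=3) == []
        (run,) = find_proline_runs(rec, min_run=2)
        assert (run.start, run.length) == (1, 2)

    def test_run_broken_by_nonstandard_letter(self):
        # X breaks a proline run just like any non-P residue
        rec = ProteinRecord(id="a", sequence="APPXPPPA")
        (run,) = find_proline_runs(rec)
        assert run.start == 4 and run.x_residue == "X"

    def test_multiple_runs_sorted(self):
        runs = find_proline_runs(ProteinRecord(id="a", sequence="TPPPAGPPPPK"))
        assert [r.start for r in runs] == [1, 6]
        assert [r.x_residue for r in runs] == ["T", "G"]

    def test_min_run_below_2_rejected(self):
        with pytest.raises(ValueError):
            find_proline_runs(ProteinRecord(id="a", sequence="PPP"), min_run=1)


@given(st.text(alphabet="PATL", min_size=1, max_size=80), st.integers(2, 4))
def test_run_detection_matches_brute_force_oracle(seq, min_run):
    rec = ProteinRecord(id="a", sequence=seq)
    got: dict[str, int] = {}
    for run in find_proline_runs(rec, min_run=min_run):
        assert set(rec.sequence[run.start : run.start + run.length]) == {"P"}
        if run.start > 0:
            assert rec.sequence[run.start - 1] != "P"
        end = run.start + run.length
        if end < len(rec.sequence):
            assert rec.sequence[end] != "P"
        got[run.x_residue] = got.get(run.x_residue, 0) + 1
    assert got == brute_force_run_counts(seq, min_run)


class TestCensus:
    def test_single_motif(self, make_records):
        c = census(make_records({"p1": "ATPPPK"}))
        assert c.observed == {"T": 1}
        assert c.n_ppp_proteins == 1
        assert c.protein_ids["T"] == {"p1"}

    def test_per_run_vs_windowed_on_tpppp(self, make_records):
        recs = make_records({"p1": "TPPPP"})
        assert census(recs, mode="per_run").observed == {"T": 1}
        assert census(recs, mode="windowed").observed == {"T": 1, "P": 1}

    def test_windowed_counts_every_window(self, make_records):
        # APPPPPA: windows A/PPP at 0; PPPP at 1,2 -> P:2
        c = census(make_records({"p1": "APPPPPA"}), mode="windowed")
        assert c.observed == {"A": 1, "P": 2}

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            census([])
        with pytest.raises(ValueError):
            census([ProteinRecord(id="a", sequence="MK")], mode="bogus")

    def test_terminal_runs_tallied_separately(self, make_records):
        c = census(make_records({"p1": "PPPA", "p2": "TPPP"}))
        assert c.observed == {"T": 1}
        assert c.n_terminal_runs == 1
        assert c.n_ppp_proteins == 2

    def test_planted_motifs_recovered_exactly(self):
        """50 planted TPPP motifs in a proline-free background are the only
        runs the census finds."""
        spec = ProteomeSpec(
            n_proteins=40, length_mean=200, length_sd=20,
            composition={"A": 0.4, "G": 0.3, "T": 0.3},
            planted=(("T", 3, 50),), seed=7,
        )
        records, truth = gen_proteome(spec)
        c = census(records)
        assert c.observed == {"T": 50}
        assert len(truth) == 50

    def test_conservation_of_run_counts(self, make_records):
        recs = make_records({"p1": "PPPATPPPAGPPP", "p2": "LPPPL"})
        c = census(recs)
        n_runs = sum(len(find_proline_runs(r)) for r in recs)
        assert sum(c.observed.values()) == n_runs - c.n_terminal_runs


class TestExpectedCount:
    @pytest.fixture
    def comp(self):
        # p = 0.1, x_A = 0.05, g = 1000
        seq = "P" * 100 + "A" * 50 + "T" * 850
        return composition([ProteinRecord(id="a", sequence=seq)])

    def test_direct_arithmetic(self, comp):
        assert expected_count(comp, "A", n_pro=3) == pytest.approx(0.05)

    def test_zero_fraction_gives_zero(self, comp):
        assert expected_count(comp, "W") == 0.0

    def test_unknown_residue_rejected(self, comp):
        with pytest.raises(ValueError):
            expected_count(comp, "X")
        with pytest.raises(ValueError):
            expected_count(comp, "A", n_pro=0)

    def test_monotonic_in_x_and_g_decreasing_in_n_pro(self, comp):
        # increasing in the X fraction
        assert expected_count(comp, "T") > expected_count(comp, "A")
        # increasing in g at fixed fractions
        bigger = composition(
            [ProteinRecord(id="a", sequence=("P" * 100 + "A" * 50 + "T" * 850) * 2)]
        )
        assert expected_count(bigger, "A") > expected_count(comp, "A")
        # decreasing in n_pro for p < 1
        assert expected_count(comp, "A", n_pro=2) > expected_count(comp, "A", n_pro=3)

    def test_n_pro_2_reproduces_squared_formula(self, comp):
        assert expected_count(comp, "A", n_pro=2) == pytest.approx(
            comp.p**2 * comp.x["A"] * comp.g
        )


class TestShuffleNull:
    def test_degenerate_proteome_gives_p_1(self, make_records):
        recs = make_records({"a": "P" * 10, "b": "P" * 8})
        null = shuffle_null(recs, "T", n_shuffles=20, seed=1)
        assert null.counts == [null.observed] * 20
        assert null.p_value == 1.0

    def test_invalid_args(self, make_records):
        recs = make_records({"a": "TPPPA"})
        with pytest.raises(ValueError):
            shuffle_null(recs, "T", n_shuffles=0, seed=1)

    def test_mean_matches_analytic_expectation(self):
        spec = ProteomeSpec(
            n_proteins=60, length_mean=500, length_sd=20,
            composition={"P": 0.05, "T": 0.06, "A": 0.89}, seed=11,
        )
        records, _ = gen_proteome(spec)
        comp = composition(records)
        null = shuffle_null(records, "T", n_shuffles=300, seed=5)
        se = np.std(null.counts, ddof=1) / np.sqrt(len(null.counts))
        assert abs(null.mean - expected_count(comp, "T")) < 3 * max(se, 0.05)

    def test_planted_excess_detected(self):
        spec = ProteomeSpec(
            n_proteins=60, length_mean=500, length_sd=20,
            composition={"P": 0.05, "T": 0.06, "A": 0.89},
            planted=(("T", 3, 40),), seed=11,
        )
        records, _ = gen_proteome(spec)
        null = shuffle_null(records, "T", n_shuffles=199, seed=5)
        assert null.observed >= 40
        assert null.p_value <= 0.01


class TestEnrichmentTable:
    def test_over_representation_ratio(self, make_records):
        # observed 17 vs expected 5 must report an enrichment ratio of 3.4
        c = census(make_records({"p1": "ATPPPK"}))
        c.observed = {"T": 17}
        c.expected = {a: 0.0 for a in STANDARD_RESIDUES}
        c.expected["T"] = 5.0
        c.expected["A"] = 2.0
        c.ratio = {
            a: (c.observed.get(a, 0) / e if e > 1e-12 else float("nan"))
            for a, e in c.expected.items()
        }
        table = enrichment_table(c)
        top = table.iloc[0]
        assert (top["X"], top["observed"], top["expected"]) == ("T", 17, 5.0)
        assert top["ratio"] == pytest.approx(3.4)
        # observed 0 with positive expectation -> ratio 0; expected ~0 -> missing
        a_row = table.set_index("X").loc["A"]
        assert a_row["ratio"] == 0.0
        assert table["ratio"].isna().sum() == 18

    def test_sorted_by_ratio_descending(self, make_records):
        recs = make_records({"p1": "ATPPPK" * 3 + "LPPPA"})
        table = enrichment_table(census(recs))
        ratios = table["ratio"].dropna().tolist()
        assert ratios == sorted(ratios, reverse=True)
        assert len(table) == 20
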