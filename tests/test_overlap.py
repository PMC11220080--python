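"""Gene-level layer joins, overlap percentages and contribution statistics."""

import numpy as np
import pandas as pd
import pytest

from rerhythm.overlap import (
    amplitude_ratio_classification,
    contribution_chain,
    join_layers,
    lead_lag_ratio,
    overlap_percentages,
)


def _fits(ids, rhythmic, phases=None, amplitudes=None):
    n = len(ids)
    return pd.DataFrame(
        {
            "consensus_rhythmic": rhythmic,
            "acrophase": phases if phases is not None else np.zeros(n),
            "amplitude": amplitudes if amplitudes is not None else np.ones(n),
        },
        index=pd.Index(ids, name="series_id"),
    )


def _map(*pairs):
    return pd.DataFrame(
        {"series_id": [p[0] for p in pairs], "gene": [p[1] for p in pairs]}
    )


class TestJoin:
    def test_any_rule_over_gene_series(self):
        mrna = _fits(["t1", "t2"], [True, False])
        te = _fits(["p1"], [False])
        ne = _fits(["q1"], [False])
        gm = _map(("t1", "gA"), ("t2", "gA"), ("p1", "gA"), ("q1", "gA"))
        j = join_layers(mrna, te, ne, gm)
        assert list(j.index) == ["gA"]
        assert j.loc["gA", "rhythmic_mrna_ALL"]
        assert not j.loc["gA", "rhythmic_te_ALL"]

    def test_disjoint_layers_give_empty_universe(self):
        mrna = _fits(["t1"], [True])
        te = _fits(["p1"], [True])
        ne = _fits(["q1"], [True])
        gm = _map(("t1", "g1"), ("p1", "g2"), ("q1", "g3"))
        j = join_layers(mrna, te, ne, gm)
        assert j.empty
        with pytest.raises(ValueError, match="empty"):
            overlap_percentages(j)

    def test_unmapped_series_rejected(self):
        mrna = _fits(["t1", "tX"], [True, False])
        gm = _map(("t1", "g1"))
        with pytest.raises(ValueError, match="tX"):
            join_layers(mrna, _fits([], []), _fits([], []), gm)

    def test_matches_brute_force_join(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(30)]
        pairs, fits = [], {}
        for layer, prefix in (("mrna", "t"), ("te", "p"), ("ne", "q")):
            ids = []
            for g in genes:
                for k in range(rng.integers(0, 3)):
                    sid = f"{prefix}_{g}_{k}"
                    ids.append(sid)
                    pairs.append((sid, g))
            fits[layer] = _fits(ids, rng.random(len(ids)) < 0.5)
        j = join_layers(fits["mrna"], fits["te"], fits["ne"], _map(*pairs))
        # brute-force nested loop
        gene_of = dict(pairs)
        for g in genes:
            series = {
                layer: [s for s in fits[layer].index if gene_of[s] == g]
                for layer in fits
            }
            in_universe = bool(series["mrna"]) and (
                bool(series["te"]) or bool(series["ne"])
            )
            assert (g in j.index) == in_universe
            if in_universe:
                for layer in fits:
                    expect = any(
                        fits[layer].loc[s, "consensus_rhythmic"] for s in series[layer]
                    )
                    assert j.loc[g, f"rhythmic_{layer}_ALL"] == expect


class TestOverlapPercentages:
    def test_subset_gives_hundred_percent(self):
        genes = [f"g{i}" for i in range(10)]
        mrna = _fits([f"t{g}" for g in genes], [False] * 10)
        te = _fits([f"p{g}" for g in genes], [True] * 10)
        ne = _fits([f"q{g}" for g in genes], [True] * 4 + [False] * 6)
        gm = _map(*[(f"{x}{g}", g) for g in genes for x in "tpq"])
        j = join_layers(mrna, te, ne, gm)
        s = overlap_percentages(j)
        assert s.pct_rhythmic_ne_with_rhythmic_te == 100.0
        assert s.n_gor_pta == 0

    def test_hand_enumerated_toy_table(self):
        genes = [f"g{i}" for i in range(10)]
        r_mrna = [True] * 4 + [False] * 6
        r_te = [True, False, True, False, True, True, False, False, False, False]
        r_ne = [True, True, False, False, False, True, True, False, False, False]
        mrna = _fits([f"t{g}" for g in genes], r_mrna)
        te = _fits([f"p{g}" for g in genes], r_te)
        ne = _fits([f"q{g}" for g in genes], r_ne)
        gm = _map(*[(f"{x}{g}", g) for g in genes for x in "tpq"])
        s = overlap_percentages(join_layers(mrna, te, ne, gm))
        # by hand: mrna-rhythmic {0,1,2,3}, te {0,2,4,5}, ne {0,1,5,6}
        assert s.pct_rhythmic_mrna_with_rhythmic_te == 50.0  # {0,2} of 4
        assert s.pct_rhythmic_te_with_rhythmic_mrna == 50.0  # {0,2} of 4
        assert s.pct_rhythmic_te_with_rhythmic_ne == 50.0  # {0,5} of 4
        assert s.pct_rhythmic_ne_with_rhythmic_te == 50.0  # {0,5} of 4
        assert s.n_gor_pta == 2  # {1,6}
        assert s.pct_contribution_chain == 25.0

    def test_complementarity_up_to_rounding(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(40)]
        mrna = _fits([f"t{g}" for g in genes], rng.random(40) < 0.5)
        te = _fits([f"p{g}" for g in genes], rng.random(40) < 0.5)
        ne = _fits([f"q{g}" for g in genes], rng.random(40) < 0.5)
        gm = _map(*[(f"{x}{g}", g) for g in genes for x in "tpq"])
        j = join_layers(mrna, te, ne, gm)
        s = overlap_percentages(j, decimals=6)
        r_ne = j["rhythmic_ne_ALL"].to_numpy()
        r_te = j["rhythmic_te_ALL"].to_numpy()
        pct_without = 100.0 * (r_ne & ~r_te).sum() / r_ne.sum()
        assert s.pct_rhythmic_ne_with_rhythmic_te + pct_without == pytest.approx(100.0)
        # population identity: acquired + shared = all nuclear-rhythmic genes
        assert s.n_gor_pta + (r_ne & r_te).sum() == r_ne.sum()


class TestContributionChain:
    def test_published_ecd_chain(self):
        assert contribution_chain(14, 27) == 3.8

    def test_trivial_and_documented_std_value(self):
        assert contribution_chain(100, 100) == 100.0
        # the rounded printed inputs give 2.9 (the unrounded publication value is 2.8)
        assert contribution_chain(6, 48) == 2.9

    def test_monotone_in_each_argument(self):
        grid = np.linspace(0, 100, 21)
        for fixed in (0.0, 37.0, 100.0):
            vals = [contribution_chain(x, fixed) for x in grid]
            assert all(b >= a for a, b in zip(vals, vals[1:]))
            vals = [contribution_chain(fixed, x) for x in grid]
            assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_range_checked(self):
        with pytest.raises(ValueError, match="outside"):
            contribution_chain(101, 50)


def _double_rhythmic_join(phase_pairs=None, amp_pairs=None):
    n = len(phase_pairs or amp_pairs)
    genes = [f"g{i}" for i in range(n)]
    phases = phase_pairs or [(0.0, 0.0)] * n
    amps = amp_pairs or [(1.0, 1.0)] * n
    mrna = _fits([f"t{g}" for g in genes], [True] * n,
                 phases=[p[0] for p in phases], amplitudes=[a[0] for a in amps])
    te = _fits([f"p{g}" for g in genes], [True] * n,
               phases=[p[1] for p in phases], amplitudes=[a[1] for a in amps])
    ne = _fits([f"q{g}" for g in genes], [False] * n)
    gm = _map(*[(f"{x}{g}", g) for g in genes for x in "tpq"])
    return join_layers(mrna, te, ne, gm)


class TestLeadLag:
    def test_transcript_leading_protein(self):
        j = _double_rhythmic_join(phase_pairs=[(4.0, 7.0)])
        assert lead_lag_ratio(j) == (1, 0, float("inf"))

    def test_transcript_lagging_protein(self):
        j = _double_rhythmic_join(phase_pairs=[(7.0, 4.0)])
        n_lead, n_lag, _ = lead_lag_ratio(j)
        assert (n_lead, n_lag) == (0, 1)

    def test_ties_count_as_lag(self):
        j = _double_rhythmic_join(phase_pairs=[(5.0, 5.0), (3.0, 15.0)])
        assert lead_lag_ratio(j)[:2] == (0, 2)

    def test_counts_match_brute_force(self):
        rng = np.random.default_rng(11)
        pairs = list(zip(rng.uniform(0, 24, 20), rng.uniform(0, 24, 20)))
        j = _double_rhythmic_join(phase_pairs=pairs)
        n_lead, n_lag, _ = lead_lag_ratio(j)
        expect_lead = sum(1 for t, p in pairs if 0 < (p - t) % 24 < 12)
        assert n_lead == expect_lead and n_lag == 20 - expect_lead

    def test_no_doubly_rhythmic_genes(self):
        mrna = _fits(["t1"], [False])
        te = _fits(["p1"], [True])
        ne = _fits(["q1"], [False])
        j = join_layers(mrna, te, ne, _map(("t1", "g"), ("p1", "g"), ("q1", "g")))
        assert np.isnan(lead_lag_ratio(j)[2])


class TestAmplitudeRatio:
    def test_equal_amplitudes_count_as_lower(self):
        j = _double_rhythmic_join(amp_pairs=[(1.0, 1.0), (2.0, 2.0)])
        assert amplitude_ratio_classification(j)[:2] == (0, 2)

    def test_hand_enumeration(self):
        amp_pairs = [(1.0, 2.0), (3.0, 1.0), (0.5, 0.6), (2.0, 2.0)]
        j = _double_rhythmic_join(amp_pairs=amp_pairs)
        n_hi, n_lo, ratio = amplitude_ratio_classification(j)
        assert (n_hi, n_lo) == (2, 2)
        assert ratio == 1.0

    def test_doubled_protein_amplitudes_dominate(self):
        rng = np.random.default_rng(13)
        a_mrna = rng.uniform(0.5, 2.0, 200)
        noise = rng.normal(1, 0.05, 200)
        amp_pairs = list(zip(a_mrna, 2 * a_mrna * noise))
        j = _double_rhythmic_join(amp_pairs=amp_pairs)
        n_hi, n_lo, ratio = amplitude_ratio_classification(j)
        assert n_hi > 190 and ratio > 1
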