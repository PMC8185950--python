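"""Dynamic-contact classification, matched nulls, phase coherence, core clock."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from rhythmhic.expression import CircadianCalls
from rhythmhic.genome import FeatureSet, GenomicInterval, RestrictionMap
from rhythmhic.io import InteractionTable
from rhythmhic.interactome import (classify_dynamic, contacts_per_timepoint,
                                   coreclock_comparison,
                                   erna_contact_enrichment,
                                   matched_null_enrichment, phase_coherence,
                                   _phase_bin)
from rhythmhic.simulate import SimConfig, simulate_pchic, simulate_truth

ZTS = (0, 6, 12, 18)


def _table(rows, fragmap, baits=None, n_reps=2):
    """rows: list of (bait, other, {zt: [counts]}, score)"""
    recs = []
    for bait, other, counts, score in rows:
        rec = {"bait_frag": bait, "other_frag": other, "score": score}
        for t in ZTS:
            for r, c in enumerate(counts[t], 1):
                rec[f"count_ZT{t}_R{r}"] = c
        d = fragmap.distance(bait, other)
        rec["distance_bp"] = np.nan if d is None else float(d)
        recs.append(rec)
    return InteractionTable(pd.DataFrame(recs), fragmap,
                            baits or {r[0] for r in rows})


class TestClassifyDynamic:
    def test_identical_counts_stable_zero_lfc(self, fragmap):
        t = _table([(0, 50, {z: [10, 10] for z in ZTS}, 6.0),
                    (1, 60, {z: [6, 6] for z in ZTS}, 6.0)],
                   fragmap)
        calls = classify_dynamic(t)
        r = calls.df.iloc[0]
        assert r["klass"] == "stable" and r["log2fc"] == 0.0

    def test_all_zero_counts_stable_p_one(self, fragmap):
        t = _table([(0, 50, {z: [0, 0] for z in ZTS}, 6.0),
                    (1, 60, {0: [5, 7], 6: [6, 6], 12: [5, 6], 18: [7, 5]}, 6.0)],
                   fragmap)
        calls = classify_dynamic(t)
        assert calls.df.iloc[0]["p"] == 1.0
        assert calls.df.iloc[0]["klass"] == "stable"

    def test_lrt_matches_deviance_oracle_at_fixed_dispersion(self, fragmap):
        counts = {0: [10, 12], 6: [11, 9], 12: [40, 44], 18: [10, 10]}
        t = _table([(0, 50, counts, 6.0)], fragmap)
        phi = 0.1
        calls = classify_dynamic(t, dispersion=phi)

        # independent oracle: numeric NB deviance with the same offsets
        y = np.array([counts[z][r] for z in ZTS for r in range(2)], float)
        totals = y  # single interaction: column totals are the counts
        s = totals / totals.mean()

        def nll(m, yy, ss):
            mu = ss * m
            r = 1.0 / phi
            p = r / (r + mu)
            return -np.sum(stats.nbinom.logpmf(yy, r, p))

        def fit(yy, ss):
            res = optimize.minimize_scalar(nll, args=(yy, ss),
                                           bounds=(1e-9, 1e6), method="bounded",
                                           options={"xatol": 1e-12})
            return -res.fun

        ll0 = fit(y, s)
        ll1 = 0.0
        for gi, z in enumerate(ZTS):
            idx = [2 * gi, 2 * gi + 1]
            ll1 += fit(y[idx], s[idx])
        oracle = 2.0 * (ll1 - ll0)
        assert abs(calls.df.iloc[0]["lrt_stat"] - oracle) < 1e-6

    def test_planted_power(self):
        # 4-fold dynamic contacts, mean 30, phi = 0.1, 3 reps: power >= 0.8
        cfg = SimConfig(seed=23, n_genes=200, circadian_fraction=0.5,
                        fraction_dynamic_contacts=0.5, dynamic_fold=4.0,
                        dispersion=0.1, contact_mean=30.0)
        truth = simulate_truth(cfg)
        table = simulate_pchic(truth)
        calls = classify_dynamic(table)
        planted = truth.interactions.set_index(["bait_frag", "other_frag"])["klass"]
        key = list(zip(calls.df["bait_frag"], calls.df["other_frag"]))
        truth_class = np.array([planted.get(k, "stable") for k in key])
        dyn = (calls.df["klass"] == "dynamic").to_numpy()
        is_dyn = truth_class == "dynamic"
        assert (dyn & is_dyn).sum() / is_dyn.sum() >= 0.8

    def test_null_table_false_call_rate_bounded(self):
        cfg = SimConfig(seed=31, n_genes=200, fraction_dynamic_contacts=0.0,
                        n_background_contacts=0)
        truth = simulate_truth(cfg)
        calls = classify_dynamic(simulate_pchic(truth), fdr=0.05)
        n = len(calls.df)
        hi = stats.binom.ppf(0.995, n, 0.05)
        assert calls.n_dynamic <= hi

    def test_partition_is_complete(self, default_truth):
        calls = classify_dynamic(simulate_pchic(default_truth))
        assert calls.n_dynamic + calls.n_stable == len(calls.df)

    def test_doubling_counts_preserves_log2fc(self, fragmap):
        counts = {0: [10, 12], 6: [11, 9], 12: [40, 44], 18: [10, 10]}
        t1 = _table([(0, 50, counts, 6.0)], fragmap)
        doubled = {z: [2 * c for c in v] for z, v in counts.items()}
        t2 = _table([(0, 50, doubled, 6.0)], fragmap)
        c1 = classify_dynamic(t1, dispersion=0.1)
        c2 = classify_dynamic(t2, dispersion=0.1)
        assert np.isclose(c1.df.iloc[0]["log2fc"], c2.df.iloc[0]["log2fc"])


class TestContactsPerTimepoint:
    def _calls(self, rows):
        df = pd.DataFrame(rows, columns=["gene_id", "phase"])
        df["circadian"] = True
        df["p"] = df["q"] = 0.0
        df["tie_flag"] = False
        df["diel"] = "diurnal"
        return CircadianCalls(df)

    def test_single_interaction_offset_zero(self, fragmap):
        rows = [(0, 50, {z: [1, 1] for z in ZTS}, 0.0)]
        t = _table(rows, fragmap)
        t.df["score_ZT6"] = 6.0
        for z in (0, 12, 18):
            t.df[f"score_ZT{z}"] = 1.0
        res = contacts_per_timepoint(t, self._calls([("g", 6)]), {"g": 0})
        assert res.per_promoter.iloc[0]["peak_zt"] == 6
        assert res.per_promoter.iloc[0]["offset"] == 0

    def test_equal_contacts_tie_flagged(self, fragmap):
        rows = [(0, 50, {z: [1, 1] for z in ZTS}, 6.0)]
        t = _table(rows, fragmap)  # same score at every ZT
        res = contacts_per_timepoint(t, self._calls([("g", 6)]), {"g": 0})
        assert res.per_promoter.iloc[0]["tie_flag"]
        assert res.offset_counts() == {0: 0, 6: 0, 12: 0}

    def test_planted_phase_locked_coupling(self, default_truth):
        from rhythmhic.expression import classify_circadian
        from rhythmhic.simulate import simulate_expression

        table = simulate_pchic(default_truth)
        calls = classify_circadian(simulate_expression(default_truth))
        gene_baits = dict(zip(default_truth.genes["gene_id"],
                              default_truth.genes["bait_frag"]))
        res = contacts_per_timepoint(table, calls, gene_baits)
        counts = res.offset_counts()
        total = sum(counts.values())
        assert counts[0] / total > 0.5
        assert res.p < 0.01


class TestMatchedNullEnrichment:
    def test_genome_tiling_features_give_ratio_one(self, default_truth):
        truth = default_truth
        table = simulate_pchic(truth)
        tiling = FeatureSet("all", [
            GenomicInterval(c, 0, truth.genome.length(c))
            for c in truth.genome.names])
        res = matched_null_enrichment(table, tiling, truth.bait_universe,
                                      truth.fragmap, n_iter=5, seed=0)
        n_uniq = table.df[np.isfinite(table.df["distance_bp"])] \
            .drop_duplicates("other_frag").shape[0]
        assert res.observed == n_uniq
        assert np.all(res.expected == n_uniq)
        assert res.ratio == 1.0
        assert res.n_skipped == 0

    def test_uniform_random_features_ratio_near_one(self, default_truth, rng):
        truth = default_truth
        table = simulate_pchic(truth)
        feats = []
        for _ in range(300):
            c = truth.genome.names[rng.integers(2)]
            s = int(rng.integers(truth.genome.length(c) - 5000))
            feats.append(GenomicInterval(c, s, s + 4000))
        res = matched_null_enrichment(table, FeatureSet("rand", feats),
                                      truth.bait_universe, truth.fragmap,
                                      n_iter=100, seed=5)
        assert abs(res.ratio - 1.0) <= 0.1

    def test_features_planted_at_other_ends_enriched(self, default_truth):
        table = simulate_pchic(default_truth)
        res = matched_null_enrichment(table, default_truth.planted_features,
                                      default_truth.bait_universe,
                                      default_truth.fragmap, n_iter=100, seed=2)
        assert res.ratio > 1.5
        assert res.t_p < 1e-6

    def test_empty_features_degenerate(self, default_truth):
        table = simulate_pchic(default_truth)
        res = matched_null_enrichment(table, FeatureSet("empty", []),
                                      default_truth.bait_universe,
                                      default_truth.fragmap, n_iter=5, seed=0)
        assert res.degenerate and res.observed == 0

    def test_too_few_iterations_rejected(self, default_truth):
        with pytest.raises(ValueError):
            matched_null_enrichment(simulate_pchic(default_truth),
                                    default_truth.planted_features,
                                    default_truth.bait_universe,
                                    default_truth.fragmap, n_iter=1)


class TestErnaEnrichment:
    def _sets(self, truth):
        enh = truth.enhancers
        osc = FeatureSet("osc", [
            GenomicInterval(r["chrom"], int(r["start"]), int(r["end"]))
            for _, r in enh[enh["oscillatory"]].iterrows()])
        non = FeatureSet("non", [
            GenomicInterval(r["chrom"], int(r["start"]), int(r["end"]))
            for _, r in enh[~enh["oscillatory"]].iterrows()])
        return osc, non

    def test_planted_wiring_enriched(self, default_truth):
        truth = default_truth
        table = simulate_pchic(truth)
        osc, non = self._sets(truth)
        circ_baits = {int(r["bait_frag"]) for _, r in
                      truth.genes[truth.genes["circadian"]].iterrows()}
        res = erna_contact_enrichment(table, osc, non, circ_baits,
                                      truth.fragmap, n_iter=100, seed=1)
        assert res.ratio > 1.0 and res.t_p < 0.01

    def test_label_shuffle_null_centred(self, default_truth, rng):
        # shuffled osc/nonosc labels: z within +/-3 in most runs
        truth = default_truth
        table = simulate_pchic(truth)
        osc, non = self._sets(truth)
        pool = osc.features + non.features
        circ_baits = {int(r["bait_frag"]) for _, r in
                      truth.genes[truth.genes["circadian"]].iterrows()}
        hits = 0
        runs = 20
        for run in range(runs):
            perm = rng.permutation(len(pool))
            o = FeatureSet("o", [pool[i] for i in perm[:len(osc)]])
            nn = FeatureSet("n", [pool[i] for i in perm[len(osc):]])
            res = erna_contact_enrichment(table, o, nn, circ_baits,
                                          truth.fragmap, n_iter=60, seed=run)
            if not np.isnan(res.z) and abs(res.z) < 3:
                hits += 1
        assert hits / runs >= 0.8

    def test_zero_circadian_baits_degenerate(self, default_truth):
        table = simulate_pchic(default_truth)
        osc, non = self._sets(default_truth)
        res = erna_contact_enrichment(table, osc, non, set(),
                                      default_truth.fragmap, n_iter=5, seed=0)
        assert res.degenerate and res.observed == 0

    def test_pool_smaller_than_osc_rejected(self, default_truth):
        osc, non = self._sets(default_truth)
        with pytest.raises(ValueError):
            erna_contact_enrichment(simulate_pchic(default_truth), osc,
                                    FeatureSet("tiny", non.features[:2]),
                                    {0}, default_truth.fragmap)


class TestPhaseCoherence:
    def test_hour_binning_rule(self):
        assert _phase_bin(0, "hr8x3") == 0
        assert _phase_bin(23.5, "hr8x3") == 7
        assert _phase_bin(3.0, "hr8x3") == 1

    def test_planted_assortative_wiring(self, default_truth):
        from rhythmhic.expression import classify_circadian
        from rhythmhic.simulate import simulate_expression

        truth = default_truth
        table = simulate_pchic(truth)
        calls = classify_circadian(simulate_expression(truth))
        gene_baits = dict(zip(truth.genes["gene_id"], truth.genes["bait_frag"]))
        enh = truth.enhancers
        targets = {int(r["frag"]): float(r["phase_hr"])
                   for _, r in enh[enh["oscillatory"]].iterrows()}
        res = phase_coherence(table, calls, gene_baits, targets, "hr8x3")
        assert not res.degenerate
        assert res.wilcoxon_p < 0.01


class TestCoreClock:
    def test_single_dynamic_contact_gives_fraction_one(self, fragmap):
        rows = [(0, 50, {0: [40, 44], 6: [10, 10], 12: [11, 9], 18: [10, 12]}, 6.0),
                (1, 70, {z: [10, 10] for z in ZTS}, 6.0),
                (2, 90, {z: [10, 11] for z in ZTS}, 6.0),
                (3, 110, {z: [11, 10] for z in ZTS}, 6.0)]
        t = _table(rows, fragmap)
        dyn = classify_dynamic(t, dispersion=0.01, fdr=0.3)
        df = pd.DataFrame({"gene_id": ["A", "b", "c", "d"],
                           "phase": [0, 6, 12, 18]})
        df["circadian"] = True
        df["p"] = df["q"] = 0.0
        df["tie_flag"] = False
        df["diel"] = "diurnal"
        calls = CircadianCalls(df)
        res = coreclock_comparison(t, calls, {"A": 0, "b": 1, "c": 2, "d": 3},
                                   dyn, core_list=("A",), n_iter=10, seed=0)
        assert dyn.df.iloc[0]["klass"] == "dynamic"
        assert res.core_dynamic_frac["A"] == 1.0

    def test_planted_core_effect_detected(self):
        # cores planted with ~0.6x contacts and boosted dynamic fraction
        cfg = SimConfig(seed=37, n_genes=300, circadian_fraction=0.4,
                        core_clock_emulation=True)
        truth = simulate_truth(cfg)
        table = simulate_pchic(truth)
        from rhythmhic.expression import classify_circadian
        from rhythmhic.simulate import simulate_expression

        calls = classify_circadian(simulate_expression(truth))
        gene_baits = dict(zip(truth.genes["gene_id"], truth.genes["bait_frag"]))
        circ_baits = {gene_baits[g] for g in calls.circadian_genes
                      if g in gene_baits}
        dyn = classify_dynamic(table, bait_filter=circ_baits)
        res = coreclock_comparison(table, calls, gene_baits, dyn,
                                   n_iter=100, seed=3)
        assert res.core_contacts.mean() < res.null_contacts.mean()
        assert res.core_dynamic_frac.mean() > res.null_dynamic_frac.mean()
        assert res.p_contacts < 0.05 and res.p_dynamic < 0.05

    def test_missing_core_genes_error(self, fragmap):
        rows = [(0, 50, {z: [1, 1] for z in ZTS}, 6.0)]
        t = _table(rows, fragmap)
        df = pd.DataFrame({"gene_id": ["x"], "phase": [0]})
        df["circadian"] = True
        df["p"] = df["q"] = 0.0
        df["tie_flag"] = False
        df["diel"] = "diurnal"
        dyn = classify_dynamic(t, dispersion=0.1)
        with pytest.raises(ValueError):
            coreclock_comparison(t, CircadianCalls(df), {"x": 0}, dyn)
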