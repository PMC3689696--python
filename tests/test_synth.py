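"""Repeat-array simulator: determinism, replay, biases, consensus, truth."""

import numpy as np
import pytest

from ribohet.recomb import incompatibility_matrix, informative_sites
from ribohet.seqio import Alignment
from ribohet.structure import fold_maxpair
from ribohet.synth import (
    ArraySimConfig,
    Stem,
    emit_consensus_with_ambiguity,
    evolve_array,
    make_master,
    replay_events,
    sample_clones,
    truth_evaluation,
)
from ribohet.variation import (
    Verdict,
    check_ambiguity_consistency,
    pairwise_differences,
    profile_variable_sites,
    substitution_spectrum,
)


class TestConfig:
    def test_seed_mandatory(self):
        with pytest.raises(ValueError):
            ArraySimConfig()

    def test_overlapping_stems_rejected(self):
        with pytest.raises(ValueError):
            ArraySimConfig(
                seed=1,
                hairpin_spec=(Stem(10, 20, 25, 35), Stem(30, 35, 40, 45)),
            )

    def test_unequal_strand_lengths_rejected(self):
        with pytest.raises(ValueError):
            Stem(10, 20, 30, 45)


class TestMaster:
    def test_spec_pairs_realized(self):
        cfg = ArraySimConfig(seed=5, master_wobble_fraction=0.0)
        seq, pt = make_master(cfg)
        wc = {"A": "T", "T": "A", "G": "C", "C": "G"}
        for stem in cfg.hairpin_spec:
            for i, j in stem.pairs:
                assert pt.partner[i - 1] == j
                assert seq[j - 1] == wc[seq[i - 1]]  # exact reverse complement

    def test_wobble_fraction_introduces_gt_pairs(self):
        cfg = ArraySimConfig(seed=5, master_wobble_fraction=1.0)
        seq, pt = make_master(cfg)
        pairs = {(seq[i - 1], seq[j - 1]) for i, j in pt.pairs}
        assert pairs == {("G", "T")}

    def test_folding_recovers_specd_stems(self):
        # an isolated, well-separated stem must dominate the fold
        cfg = ArraySimConfig(
            seed=0, repeat_length=60, hairpin_spec=(Stem(10, 19, 30, 39),),
            master_wobble_fraction=0.0,
        )
        hits = 0
        for s in range(25):
            seq, pt = make_master(ArraySimConfig(**{**cfg.__dict__, "seed": s}))
            window = seq[9:39]
            folded = fold_maxpair(window, offset=10)
            want = set(Stem(10, 19, 30, 39).pairs)
            got = {
                (folded.amplicon_position(i), folded.amplicon_position(j))
                for i, j in folded.pairs
            }
            if want <= got:
                hits += 1
        assert hits >= 20  # random flanks occasionally beat a 10-bp stem


class TestEvolve:
    def test_no_mutation_all_identical(self):
        cfg = ArraySimConfig(seed=3, mu=0.0)
        arr = evolve_array(cfg)
        assert set(arr.repeats) == {arr.master}
        assert not [e for e in arr.events if e.kind == "substitution"]

    def test_event_log_replay_reproduces_array(self):
        cfg = ArraySimConfig(seed=11, rec_rate=0.2, conv_rate=0.1)
        arr = evolve_array(cfg)
        assert replay_events(arr.master, cfg.n_repeats, arr.events) == arr.repeats

    def test_same_seed_byte_identical(self):
        a1 = evolve_array(ArraySimConfig(seed=21))
        a2 = evolve_array(ArraySimConfig(seed=21))
        assert a1.repeats == a2.repeats and a1.events == a2.events

    def test_recombination_raises_incompatibility(self):
        # paired seeds; compare fraction of incompatible informative pairs
        worse = 0
        n = 20
        for s in range(n):
            fracs = []
            for rec in (0.0, 0.5):
                arr = evolve_array(ArraySimConfig(seed=400 + s, rec_rate=rec))
                clones = sample_clones(arr, 18, seed=500 + s)
                aln = Alignment(records=tuple(clones))
                sites = informative_sites(aln)
                if len(sites) < 2:
                    fracs.append(0.0)
                    continue
                m = incompatibility_matrix(sites)
                k = len(sites)
                fracs.append(m.sum() / (k * (k - 1)))
            if fracs[1] > fracs[0]:
                worse += 1
        assert worse >= int(0.7 * n)

    def test_mean_pairwise_difference_monotone_in_mu(self):
        means = []
        for mu in (0.0005, 0.001, 0.002):
            vals = []
            for s in range(5):
                arr = evolve_array(ArraySimConfig(seed=600 + s, mu=mu))
                clones = sample_clones(arr, 12, seed=700 + s)
                pw = pairwise_differences(Alignment(records=tuple(clones)))
                n = len(pw.labels)
                vals.append(pw.substitutions.sum() / (n * (n - 1)))
            means.append(np.mean(vals))
        assert means[0] <= means[1] <= means[2]


class TestSampling:
    def test_oversampling_allows_duplicates(self):
        arr = evolve_array(ArraySimConfig(seed=2, n_repeats=3))
        clones = sample_clones(arr, 10, seed=1)
        assert len(clones) == 10

    def test_same_seed_same_sample(self):
        arr = evolve_array(ArraySimConfig(seed=2))
        c1 = sample_clones(arr, 6, seed=9)
        c2 = sample_clones(arr, 6, seed=9)
        assert [c.seq for c in c1] == [c.seq for c in c2]

    def test_full_homogenization_collapses_clones(self):
        arr = evolve_array(ArraySimConfig(seed=2, homogenization_p=1.0))
        # every new variant is immediately overwritten by the majority allele;
        # residual variation can only come from the final generation
        clones = sample_clones(arr, 8, seed=3)
        diffs = pairwise_differences(Alignment(records=tuple(clones)))
        assert diffs.max_substitutions <= 2


class TestConsensus:
    @pytest.mark.parametrize(
        "column,expected",
        [(("A", "G"), "R"), (("A",), "A"), (("A", "C", "T"), "H")],
    )
    def test_minimal_codes(self, column, expected):
        rec, flagged = emit_consensus_with_ambiguity(list(column))
        assert rec.seq == expected
        assert flagged == ()

    def test_gap_columns_flagged(self):
        rec, flagged = emit_consensus_with_ambiguity(["A-G", "AAG"])
        assert rec.seq == "A-G"
        assert flagged == (2,)

    def test_round_trip_all_verdicts_consistent(self):
        arr = evolve_array(ArraySimConfig(seed=31))
        cons, _ = emit_consensus_with_ambiguity(arr.repeats)
        recs = [
            r for r in sample_clones(arr, 18, seed=32)
        ]
        aln = Alignment(records=tuple(recs))
        grouping = {r.id: "sim" for r in recs}
        sites = profile_variable_sites(aln, grouping)
        checks = check_ambiguity_consistency(cons, sites, aln, grouping)
        ambiguous = [c for c in checks if len(c.expansion) > 1]
        # consensus is over the whole array; sampled clones cannot show a
        # state outside the column's base set, so nothing is inconsistent
        assert all(c.verdict is not Verdict.inconsistent for c in checks)
        assert ambiguous  # the run does produce ambiguity codes


class TestTruth:
    def test_zero_mu_trivially_perfect(self):
        arr = evolve_array(ArraySimConfig(seed=41, mu=0.0))
        clones = sample_clones(arr, 6, seed=42)
        summary = truth_evaluation(arr, [], clones)
        assert summary["n_true_polymorphic"] == 0
        assert summary["sensitivity"] == 1.0

    def test_detected_positions_match_truth(self):
        arr = evolve_array(ArraySimConfig(seed=43))
        clones = sample_clones(arr, 18, seed=44)
        aln = Alignment(records=tuple(clones))
        grouping = {r.id: "sim" for r in clones}
        sites = profile_variable_sites(aln, grouping)
        summary = truth_evaluation(arr, [s.position for s in sites], clones)
        assert summary["sensitivity"] == 1.0
        assert summary["specificity"] == 1.0

    def test_wobble_modal_among_detected_stem_variants(self):
        # strong pyrimidine-opposite-G rate multiplier: the analysis should
        # classify most detected stem variants as wobble-neutral
        from collections import Counter

        from ribohet.alphabet import canon
        from ribohet.structure import SiteRole, classify_structural_effect, map_site_context

        counts: Counter = Counter()
        for s in range(10):
            arr = evolve_array(
                ArraySimConfig(seed=800 + s, tc_opposite_g_bias=10.0)
            )
            clones = sample_clones(arr, 18, seed=900 + s)
            aln = Alignment(records=tuple(clones))
            grouping = {r.id: "sim" for r in clones}
            sites = profile_variable_sites(aln, grouping)
            ctxs = map_site_context(arr.pair_table, sites, aln)
            for site, ctx in zip(sites, ctxs):
                if ctx.role not in (SiteRole.stem_backfold, SiteRole.stem_forward):
                    continue
                joint = None
                if ctx.partner_position is not None:
                    c1 = aln.column_of_position(site.position)
                    c2 = aln.column_of_position(ctx.partner_position)
                    joint = {
                        (canon(r.seq[c1 - 1]), canon(r.seq[c2 - 1]))
                        for r in aln.records
                    }
                counts[classify_structural_effect(site, ctx, joint).effect.value] += 1
        assert counts["wobble_neutral"] == max(counts.values())

    def test_phi_verdict_scored_against_generating_process(self):
        arr = evolve_array(ArraySimConfig(seed=45, rec_rate=0.5))
        clones = sample_clones(arr, 12, seed=46)
        summary = truth_evaluation(arr, [], clones, phi_significant=True)
        assert summary["recombination_simulated"] is True
        assert summary["phi_verdict_correct"] is True
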