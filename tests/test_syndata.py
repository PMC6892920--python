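"""Generator contracts: planted constraints, truth completeness, determinism."""

import numpy as np
import pytest

from mslinc.annotation import distance_to_nearest_known, write_gtf
from mslinc.codepot import longest_orf
from mslinc.syndata import (
    SimulationDesign,
    _coding_sequence,
    _noncoding_sequence,
    generate_annotation,
    generate_expression,
    generate_survival,
    simulate,
)


class TestDesign:
    def test_sample_accounting(self, design):
        assert design.n_samples == 33
        assert len(design.groups) == 11

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            SimulationDesign(n_novel_lincrna=-1)

    def test_overallocation_rejected(self):
        with pytest.raises(ValueError):
            SimulationDesign(n_novel_lincrna=10, ms_lincrna_per_subtype=5)


class TestAnnotation:
    def test_counts_echo_design(self, study):
        truth, design = study.truth, study.design
        assert len(truth.novel_lincrna_ids) == design.n_novel_lincrna
        assert len(truth.decoy_near_ids) == design.n_decoy_near
        assert len(truth.decoy_short_ids) == design.n_decoy_short
        assert len(truth.decoy_coding_ids) == design.n_decoy_coding

    def test_geometric_constraints_by_construction(self, study):
        for tid in study.truth.novel_lincrna_ids:
            t = study.novel[tid]
            assert distance_to_nearest_known(t, study.known) >= 2000
            assert t.mature_length >= 200
        for tid in study.truth.decoy_near_ids:
            assert distance_to_nearest_known(study.novel[tid], study.known) < 2000
        for tid in study.truth.decoy_short_ids:
            assert study.novel[tid].mature_length < 200

    def test_mostly_single_exon(self, study):
        n_single = sum(
            1 for tid in study.truth.novel_lincrna_ids
            if study.novel[tid].n_exons == 1
        )
        assert n_single / len(study.truth.novel_lincrna_ids) >= 0.88

    def test_ms_map_disjoint_across_subtypes(self, study):
        seen = set()
        for ids in study.truth.ms_lincrna_map.values():
            assert not (set(ids) & seen)
            seen |= set(ids)

    def test_truth_ids_exist_in_catalogs(self, study):
        all_ids = set(study.known.ids) | set(study.novel.ids)
        truth = study.truth
        referenced = (
            set(truth.novel_lincrna_ids)
            | set(truth.decoy_near_ids)
            | set(truth.decoy_short_ids)
            | set(truth.decoy_coding_ids)
            | {m for ids in truth.ms_lincrna_map.values() for m in ids}
            | {x for l, g, _ in truth.cis_pairs for x in (l, g)}
            | set(truth.planted_class)
            | {t for t, _, _ in truth.meth_regulated}
        )
        assert referenced <= all_ids

    def test_deterministic_gtf_output(self, design, tmp_path):
        a, b = tmp_path / "a.gtf", tmp_path / "b.gtf"
        k1, n1, _ = generate_annotation(design)
        k2, n2, _ = generate_annotation(design)
        write_gtf(list(k1) + list(n1), a)
        write_gtf(list(k2) + list(n2), b)
        assert a.read_bytes() == b.read_bytes()


class TestSequences:
    def test_coding_sequence_has_covering_orf(self):
        rng = np.random.default_rng(0)
        for length in (900, 1200, 333):
            seq = _coding_sequence(length, rng)
            orf_len, cov, _, _ = longest_orf(seq)
            assert len(seq) == length
            assert cov >= 0.6

    def test_noncoding_orf_capped(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            seq = _noncoding_sequence(int(rng.integers(300, 2000)), rng)
            assert longest_orf(seq)[0] < 300

    def test_sequence_lengths_match_catalog(self, study):
        for t in list(study.known)[:20] + list(study.novel)[:20]:
            assert len(study.sequences[t.id]) == t.mature_length

    def test_same_seed_same_fasta(self, design, study):
        again = simulate(design)
        assert again.sequences == study.sequences


class TestExpression:
    def test_planted_subtype_effect_size(self, study):
        meta, fpkm = study.meta, study.fpkm
        for subtype, ids in study.truth.ms_lincrna_map.items():
            inside = meta.index[meta.group == subtype]
            outside = meta.index[meta.group != subtype]
            for tid in ids:
                diff = np.log2(fpkm.loc[tid, inside]).mean() - np.log2(
                    fpkm.loc[tid, outside]
                ).mean()
                assert diff == pytest.approx(3.0, abs=1.2)

    def test_nonnegative_and_complete(self, study):
        assert (study.fpkm.to_numpy() >= 0).all()
        assert not study.fpkm.isna().any().any()
        assert list(study.fpkm.columns) == list(study.meta.index)

    def test_zero_noise_degenerate_case(self):
        d = SimulationDesign(
            seed=3, noise_sd_log2=0.0, ms_lincrna_per_subtype=0,
            cis_pair_fraction=0.0, n_class_transcripts=0,
            n_coding_coexpressed_pairs=0,
        )
        known, novel, truth = generate_annotation(d)
        fpkm, _ = generate_expression(d, truth, known, novel)
        assert (fpkm.nunique(axis=1) == 1).all()

    def test_cis_pair_sample_correlation_distribution(self):
        """Planted latent r=0.8 keeps sample r inside [0.5, 0.95] in >= 90%
        of replicates at n=33 (Monte-Carlo over fresh latent draws)."""
        from scipy import stats as ss

        from mslinc.syndata import _latent_loading

        rng = np.random.default_rng(4)
        sd = 0.5
        a = _latent_loading(0.8, sd)
        inside = 0
        reps = 500
        for _ in range(reps):
            z = rng.normal(size=33)
            x = 2.0 ** (1.0 + a * z + rng.normal(0, sd, 33))
            y = 2.0 ** (3.0 + a * z + rng.normal(0, sd, 33))
            r = ss.pearsonr(x, y)[0]
            inside += 0.5 < r < 0.95
        assert inside / reps >= 0.90


class TestMethylationAndSurvival:
    def test_betas_in_unit_interval(self, study):
        b = study.beta.to_numpy()
        assert ((b > 0) & (b < 1)).all()

    def test_regulated_cpgs_in_window(self, study):
        catalog = {t.id: t for t in list(study.known) + list(study.novel)}
        pos = study.cpg["start"]
        for tid, cg, _ in study.truth.meth_regulated:
            t = catalog[tid]
            d = abs(pos[cg] - t.tss)
            assert 500 <= d <= 2000

    def test_no_censoring_all_events(self, study):
        import pandas as pd

        d = SimulationDesign(seed=5, censor_horizon=np.inf)
        labels = pd.Series(["a"] * 20 + ["b"] * 20, index=range(40))
        surv = generate_survival(d, labels)
        assert (surv.event == 1).all()
        assert (surv.time >= 0).all()

    def test_hazard_ratio_planted(self):
        import pandas as pd

        d = SimulationDesign(seed=6, hazard_ratio_range=(1.0, 3.0), censor_horizon=np.inf)
        labels = pd.Series(["a"] * 4000 + ["b"] * 4000, index=range(8000))
        surv = generate_survival(d, labels)
        mean_a = surv.time[labels == "a"].mean()
        mean_b = surv.time[labels == "b"].mean()
        assert mean_a / mean_b == pytest.approx(3.0, rel=0.15)


class TestPpi:
    def test_simple_graph(self, study):
        assert (study.ppi.id1 != study.ppi.id2).all()
        assert len(study.ppi_set) == len(study.ppi)

    def test_planted_pairs_respected(self, study):
        for a, b, with_ppi in study.truth.coding_coexpressed_pairs:
            assert (frozenset((a, b)) in study.ppi_set) == with_ppi

    def test_same_seed_same_edges(self, design, study):
        again = simulate(design)
        assert study.ppi.equals(again.ppi)
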