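"""Generator contracts: determinism, truth-label completeness, planted
statistical structure."""

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from diapipe.simulate import (
    ConfigError,
    SimConfig,
    draw_library_counts,
    draw_nb_counts,
    generate_contig_sets,
    generate_reads,
    generate_references,
    simulate_to_dir,
)


def _dir_digest(path: Path) -> dict[str, str]:
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(path.iterdir())
    }


def test_same_seed_gives_byte_identical_outputs(tmp_path):
    cfg = SimConfig(seed=3, n_genes=12, n_scaffolds=2, mean_library_size=300)
    simulate_to_dir(cfg, tmp_path / "a")
    simulate_to_dir(cfg, tmp_path / "b")
    assert _dir_digest(tmp_path / "a") == _dir_digest(tmp_path / "b")


def test_zero_genes_gives_empty_references(tmp_path):
    cfg = SimConfig(seed=1, n_genes=0, n_scaffolds=1, mean_library_size=0)
    truth = generate_references(cfg)
    assert truth.transcripts == {} and truth.proteins == {}
    simulate_to_dir(cfg, tmp_path)
    assert (tmp_path / "proteins.fasta").read_text() == ""
    models = pd.read_csv(tmp_path / "gene_models.tsv", sep="\t")
    assert len(models) == 0


def test_invalid_config_names_the_field():
    with pytest.raises(ConfigError, match="chimera_rate"):
        SimConfig(chimera_rate=1.5).validate()
    with pytest.raises(ConfigError, match="n_libraries"):
        SimConfig(n_libraries=10).validate()


def test_pathway_members_are_known_genes():
    truth = generate_references(SimConfig(seed=2, n_genes=50, mean_library_size=0))
    gene_ids = set(truth.gene_ids)
    members = set().union(*truth.pathways.values())
    assert members <= gene_ids


def test_gene_models_do_not_overlap_and_proteins_translate(small_truth):
    from diapipe.align import translate

    by_scaffold = {}
    for m in small_truth.gene_models:
        by_scaffold.setdefault(m.scaffold, []).append((m.start, m.end))
    for spans in by_scaffold.values():
        spans.sort()
        assert all(a_end <= b_start for (_, a_end), (b_start, _) in zip(spans, spans[1:]))
    for gid, cds in small_truth.cds.items():
        assert translate(cds)[:-1] == small_truth.proteins[f"PROT_{gid}"]


class TestContigSets:
    def test_zero_chimera_rate_plants_no_chimeras(self):
        cfg = SimConfig(seed=5, n_genes=30, chimera_rate=0.0, mean_library_size=0)
        truth = generate_references(cfg)
        _, labels = generate_contig_sets(truth, cfg)
        assert (labels["kind"] == "chimera").sum() == 0

    def test_duplicate_count_within_binomial_bounds(self):
        cfg = SimConfig(
            seed=6, n_genes=100, n_stages=1, contig_redundancy_rate=0.5,
            fragment_rate=0.0, utr_contig_rate=0.0, chimera_rate=0.0,
            mean_library_size=0,
        )
        truth = generate_references(cfg)
        _, labels = generate_contig_sets(truth, cfg)
        n_dup = int((labels["kind"] == "duplicate").sum())
        lo, hi = stats.binom.ppf([0.005, 0.995], 100, 0.5)
        assert lo <= n_dup <= hi

    def test_truth_labels_cover_every_contig(self, small_truth, small_contigs):
        by_stage, labels = small_contigs
        emitted = {c.id for contigs in by_stage.values() for c in contigs}
        assert emitted == set(labels["contig_id"])

    def test_non_chimeric_contigs_match_their_source(self, small_truth, small_contigs):
        by_stage, labels = small_contigs
        info = labels.set_index("contig_id")
        for contigs in by_stage.values():
            for c in contigs:
                kind = info.at[c.id, "kind"]
                if kind in ("full", "fragment"):
                    assert c.seq in small_truth.transcripts[info.at[c.id, "gene_id"]]
                elif kind == "utr":
                    model = next(
                        m for m in small_truth.gene_models
                        if m.gene_id == info.at[c.id, "gene_id"]
                    )
                    scaffold = small_truth.scaffolds[model.scaffold]
                    assert c.seq in scaffold
                    pos = scaffold.find(c.seq)
                    dist = max(model.start - (pos + len(c.seq)), pos - model.end)
                    assert dist <= 1000


class TestCounts:
    def test_nb_moments_match_mean_variance_relation(self):
        rng = np.random.default_rng(0)
        mu, phi = 60.0, 0.15
        draws = draw_nb_counts(np.full(4000, mu), phi, rng)
        expected_var = mu + mu * mu * phi
        assert abs(draws.mean() - mu) / mu < 0.05
        assert abs(draws.var() - expected_var) / expected_var < 0.15

    def test_null_config_shows_no_planted_signal(self):
        """With all effects zero, a two-group NB comparison should be
        non-significant for >= 94% of genes at alpha = 0.05."""
        cfg = SimConfig(
            seed=9, n_genes=150, mean_library_size=30_000,
            effect_log2fc={"photoperiod": 0.0, "bloodmeal": 0.0, "interaction": 0.0},
        )
        truth = generate_references(cfg)
        sd = np.column_stack([
            draw_library_counts(truth, cfg, "SD_NB", np.random.default_rng([9, i])).to_numpy()
            for i in range(8)
        ])
        ld = np.column_stack([
            draw_library_counts(truth, cfg, "LD_NB", np.random.default_rng([9, 100 + i])).to_numpy()
            for i in range(8)
        ])
        _, p = stats.ttest_ind(sd, ld, axis=1)
        assert (p > 0.05).mean() >= 0.94

    def test_planted_photoperiod_effect_has_expected_ratio(self):
        cfg = SimConfig(seed=12, n_genes=80, mean_library_size=50_000)
        truth = generate_references(cfg)
        up = truth.planted_lfc.index[truth.planted_lfc["photoperiod"] == 2.0]
        assert len(up) > 0
        n_rep = 25
        sd = np.mean([
            draw_library_counts(truth, cfg, "SD_NB", np.random.default_rng([1, i]))[up].to_numpy()
            for i in range(n_rep)
        ], axis=0)
        ld = np.mean([
            draw_library_counts(truth, cfg, "LD_NB", np.random.default_rng([2, i]))[up].to_numpy()
            for i in range(n_rep)
        ], axis=0)
        ratios = sd / np.maximum(ld, 1e-9)
        # library-size renormalization compresses the marginal ratio a bit,
        # so the check is on the right scale rather than a tight CI
        assert 2.5 < np.median(ratios) < 6.0


class TestReads:
    def test_zero_library_size_gives_empty_valid_fastq(self, tmp_path):
        cfg = SimConfig(seed=7, n_genes=5, mean_library_size=0)
        simulate_to_dir(cfg, tmp_path)
        fq = tmp_path / "SD_BM_1_R1.fastq"
        assert fq.exists() and fq.read_text() == ""

    def test_short_transcripts_are_skipped_with_warning(self, caplog):
        cfg = SimConfig(seed=8, n_genes=6, mean_library_size=400, insert_mean=10_000)
        truth = generate_references(cfg)
        with caplog.at_level("WARNING", logger="diapipe.simulate"):
            libs, _, counts = generate_reads(truth, cfg)
        assert sum(len(p) for p in libs.values()) == 0
        assert counts.to_numpy().sum() == 0
        assert "shorter than mean insert" in caplog.text

    def test_every_read_is_traceable_to_gene_or_contaminant(self, small_truth, small_config):
        libs, design, _ = generate_reads(small_truth, small_config)
        genes = set(small_truth.gene_ids)
        for lib, pairs in list(libs.items())[:2]:
            for pair in pairs:
                source = pair.id.split(":")[1]
                assert source in genes or source in ("vector", "adapter")

    def test_qualities_decay_toward_three_prime(self, small_truth, small_config):
        libs, _, _ = generate_reads(small_truth, small_config)
        pairs = libs["SD_BM_1"]
        full = [p.r1.qual for p in pairs if len(p.r1.qual) == small_config.read_length]
        q = np.mean(np.stack(full), axis=0)
        assert q[:20].mean() - q[-20:].mean() > 8
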