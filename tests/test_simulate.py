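"""Generator correctness: boundary physics, tag conservation, determinism."""

import dataclasses

import numpy as np
import pytest

from exofoot.core import GenomeModel, Promoter
from exofoot.errors import ConfigError, DataError
from exofoot.simulate import (
    BoundaryPair,
    FootprintModel,
    MixtureComponent,
    SimConfig,
    build_sim_genome,
    default_models,
    default_presets,
    emit_tags,
    sample_boundaries,
    simulate,
)

from helpers import bare_genome, digest_fragment, fixed_model, mirror_promoters


# ---------------------------------------------------------------------------
# models / registry
# ---------------------------------------------------------------------------


class TestRegistry:
    def test_required_presets_present(self, registry):
        required = {"sigma70", "crp_activating", "crp_repressing", "rifampicin",
                    "repressor", "ar1", "ar2", "ar1ar2"}
        assert required <= set(registry)
        assert required <= set(default_presets())

    def test_rifampicin_downstream_boundary_capped(self, registry, rng):
        model = registry["rifampicin"]
        assert max(c.hi for c in model.d_mixture) <= 25
        draws = [sample_boundaries(model, rng).d for _ in range(500)]
        assert max(draws) <= 25

    def test_mutants_spare_class_iii(self):
        presets = default_presets()
        for name in ("ar1", "ar2", "ar1ar2"):
            assert "crp_classIII" not in presets[name].drop
        assert presets["ar1ar2"].drop == {"crp_classI": 0.822, "crp_classII": 0.822}

    def test_invalid_mixture_weights_rejected(self):
        with pytest.raises(ConfigError):
            FootprintModel(name="bad",
                           u_mixture=[MixtureComponent(0.5, -10, 1.0)],
                           d_mixture=[MixtureComponent(1.0, 20, 1.0)])

    def test_boundary_pair_ordering_enforced(self):
        with pytest.raises(DataError):
            BoundaryPair(u=5, d=5)


# ---------------------------------------------------------------------------
# sample_boundaries
# ---------------------------------------------------------------------------


class TestSampleBoundaries:
    def test_degenerate_mixture_is_deterministic(self, rng):
        model = fixed_model(-10, 20)
        for _ in range(10):
            pair = sample_boundaries(model, rng)
            assert (pair.u, pair.d) == (-10, 20)

    def test_downstream_mean_matches_configuration(self, registry):
        # Monte-Carlo against the configured d mean of the sigma70 preset
        rng = np.random.default_rng(7)
        model = registry["sigma70"]
        draws = np.array([sample_boundaries(model, rng).d for _ in range(10_000)])
        assert abs(draws.mean() - 20) < 0.5

    def test_motif_protection_fixes_width(self, registry, rng):
        model = registry["repressor"]  # half-width 15
        for _ in range(50):
            pair = sample_boundaries(model, rng)
            assert pair.d - pair.u == 30

    def test_half_integer_motif_center_keeps_width(self, rng):
        model = dataclasses.replace(default_models()["crp_motif"])
        pair = sample_boundaries(model, rng)
        assert (pair.u, pair.d) == (-76, -46)
        assert pair.d - pair.u == 30


# ---------------------------------------------------------------------------
# build_sim_genome
# ---------------------------------------------------------------------------


class TestBuildSimGenome:
    def test_minimal_single_promoter(self):
        cfg = SimConfig(preset="sigma70", n_promoters=1, genome_length=1000,
                        min_spacing=500, seed=0, embed_elements=False,
                        with_sequence=False)
        genome, promoters, _ = build_sim_genome(cfg)
        assert genome.length == 1000
        assert len(promoters) == 1

    def test_single_class_composition_places_class_i_sites(self):
        cfg = SimConfig(preset="crp_activating", n_promoters=10, seed=3,
                        composition={"crp_classI": 1.0}, embed_elements=False)
        genome, promoters, truth = build_sim_genome(cfg)
        assert all(p.label == "crp_classI" for p in promoters)
        assert len(truth.sites) == 10
        assert all(s["offset"] == -61.5 for s in truth.sites)
        # the embedded 22-mer occupies offsets -72..-51 around each TSS
        for s, p in zip(truth.sites, promoters):
            expected = p.tss + (-61.5 if p.strand == "+" else 61.5)
            assert s["center"] == expected

    def test_identical_seed_reproduces_everything(self):
        cfg = SimConfig(preset="crp_activating", n_promoters=20, seed=9)
        a = build_sim_genome(cfg)
        b = build_sim_genome(cfg)
        assert a[0].sequence == b[0].sequence
        assert [(p.id, p.tss, p.strand, p.label) for p in a[1]] == \
               [(p.id, p.tss, p.strand, p.label) for p in b[1]]
        assert a[2].sites == b[2].sites

    def test_min_spacing_respected(self):
        cfg = SimConfig(preset="sigma70", n_promoters=50, min_spacing=800,
                        genome_length=60_000, seed=5, with_sequence=False)
        _, promoters, _ = build_sim_genome(cfg)
        tss = sorted(p.tss for p in promoters)
        assert min(np.diff(tss)) >= 800

    def test_infeasible_spacing_is_an_error(self):
        cfg = SimConfig(preset="sigma70", n_promoters=100, genome_length=5_000,
                        min_spacing=1000, seed=0)
        with pytest.raises(ConfigError):
            build_sim_genome(cfg)

    def test_unknown_config_keys_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig.from_dict({"preset": "sigma70", "n_promoter": 5})


# ---------------------------------------------------------------------------
# emit_tags
# ---------------------------------------------------------------------------


class TestEmitTags:
    def test_plus_promoter_boundary_mapping(self):
        genome = bare_genome(1000)
        prom = Promoter(id="p", tss=500, strand="+", label="m")
        track, _ = emit_tags(genome, [prom], {"m": fixed_model(-10, 20)}, seed=1)
        assert track.forward[490] == 1 and track.forward.sum() == 1
        assert track.reverse[520] == 1 and track.reverse.sum() == 1

    def test_minus_promoter_matches_digestion_oracle(self):
        genome = bare_genome(1000)
        prom = Promoter(id="p", tss=500, strand="-", label="m")
        track, _ = emit_tags(genome, [prom], {"m": fixed_model(-10, 20)}, seed=1)
        fwd, rev = digest_fragment(500, "-", -10, 20, 1000)
        assert (fwd, rev) == (480, 510)
        assert track.forward[fwd] == 1 and track.reverse[rev] == 1
        assert track.total() == 2

    def test_background_only_limit(self):
        genome = bare_genome(5000)
        prom = Promoter(id="p", tss=2500, strand="+", label="m")
        model = fixed_model(-10, 20, n_fragments=200, background=1.0)
        track, truth = emit_tags(genome, [prom], {"m": model}, seed=2)
        assert truth.n_signal_tags == 0
        assert track.total() == 400  # totals match the drawn fragment count

    def test_tag_conservation_and_strand_balance(self, sigma70_small):
        truth = sigma70_small.truth
        track = sigma70_small.track
        n_signal_frag = sum(truth.signal_fragments.values())
        assert truth.n_signal_tags == 2 * n_signal_frag
        assert track.total() == truth.n_signal_tags + truth.n_background_tags
        # signal forward and reverse totals are equal, so any imbalance in the
        # full track comes from the uniformly-stranded background
        imbalance = abs(int(track.forward.sum()) - int(track.reverse.sum()))
        assert imbalance <= truth.n_background_tags

    def test_unknown_label_is_an_error(self):
        genome = bare_genome(100)
        prom = Promoter(id="p", tss=50, strand="+", label="mystery")
        with pytest.raises(DataError):
            emit_tags(genome, [prom], {"m": fixed_model(-5, 5)}, seed=0)

    def test_determinism(self):
        genome = bare_genome(20_000)
        promoters = [Promoter(id=f"p{i}", tss=2000 + 3000 * i,
                              strand="+-"[i % 2], label="sigma70")
                     for i in range(5)]
        models = default_models()
        t1, tr1 = emit_tags(genome, promoters, models, seed=77)
        t2, tr2 = emit_tags(genome, promoters, models, seed=77)
        assert np.array_equal(t1.forward, t2.forward)
        assert np.array_equal(t1.reverse, t2.reverse)
        for pid in tr1.fragments:
            assert np.array_equal(tr1.fragments[pid], tr2.fragments[pid])

    def test_strand_mirror_invariance(self, registry):
        # mirroring the genome and flipping promoter strands mirrors the track
        length = 30_000
        genome = bare_genome(length)
        promoters = [Promoter(id=f"p{i}", tss=3000 + 4000 * i,
                              strand="+-"[i % 2], label="m")
                     for i in range(6)]
        model = dataclasses.replace(registry["sigma70"], name="m",
                                    background_fraction=0.0)
        fwd_run, _ = emit_tags(genome, promoters, {"m": model}, seed=5)
        mirrored, _ = emit_tags(genome, mirror_promoters(promoters, length),
                                {"m": model}, seed=5)
        assert np.array_equal(mirrored.forward, fwd_run.mirrored().forward)
        assert np.array_equal(mirrored.reverse, fwd_run.mirrored().reverse)

    def test_replicates_share_fragments_not_noise(self):
        genome = bare_genome(20_000)
        promoters = [Promoter(id=f"p{i}", tss=2000 + 3000 * i, strand="+",
                              label="sigma70") for i in range(5)]
        models = default_models()
        t0, tr0 = emit_tags(genome, promoters, models, seed=3, replicate=0)
        t1, tr1 = emit_tags(genome, promoters, models, seed=3, replicate=1)
        for pid in tr0.fragments:
            assert np.array_equal(tr0.fragments[pid], tr1.fragments[pid])
        assert not np.array_equal(t0.forward, t1.forward)


# ---------------------------------------------------------------------------
# full runs
# ---------------------------------------------------------------------------


class TestSimulate:
    def test_silenced_promoters_emit_nothing(self):
        result = simulate(SimConfig(preset="crp_repressing", n_promoters=30,
                                    seed=4, with_sequence=False))
        for pid in result.truth.dropped:
            assert result.truth.signal_fragments[pid] == 0
        kept = [p for p in result.promoters if p.id not in result.truth.dropped]
        assert all(p.label == "crp_classIII" for p in kept)

    def test_background_share_near_configured_fraction(self, sigma70_small):
        truth = sigma70_small.truth
        share = truth.n_background_tags / (truth.n_background_tags +
                                           truth.n_signal_tags)
        assert abs(share - 0.10) < 0.02
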