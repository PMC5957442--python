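"""Synthetic ChIP-exo data generator with known ground truth.

The generative model encodes lambda-exonuclease boundary physics: each
immunoprecipitated fragment is a protected duplex interval; the enzyme
digests each strand 5'->3' up to the protection, so one 5' tag lands on the
forward strand at the LEFT protected boundary and one on the reverse strand
at the RIGHT boundary.  Boundaries are drawn per fragment in TSS-relative
offsets from a factor/condition-specific :class:`FootprintModel` (a mixture
over transcription-initiation intermediate geometries, or an exact
motif-centered interval), jittered, and mapped through the promoter strand.

Randomness uses one run seed with hierarchical per-promoter substreams, so
adding promoters never reshuffles earlier ones, and a ``replicate`` index
re-randomizes tag-level noise (jitter, background routing) while keeping the
underlying fragments fixed — the construction used for replicate-correlation
analyses.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import yaml

from .core import GenomeModel, Promoter, TagTrack
from .errors import ConfigError, DataError, SimulationError
from . import motifs

_MAX_RETRIES = 100

# substream tags for hierarchical seeding
_S_GENOME, _S_FRAG, _S_TAG, _S_DROP = 0, 1, 2, 3


@dataclass(frozen=True)
class MixtureComponent:
    weight: float
    mean: float
    sd: float
    lo: float = -np.inf
    hi: float = np.inf


@dataclass(frozen=True)
class BoundaryPair:
    """Protected-interval boundaries in TSS-relative bp; always u < d."""

    u: int
    d: int

    def __post_init__(self) -> None:
        if self.u >= self.d:
            raise DataError(f"boundary pair requires u < d, got ({self.u}, {self.d})")


@dataclass
class FootprintModel:
    """Generative description of protected-interval boundaries for one factor.

    Either both boundary mixtures are given, or ``motif_protection``
    (TSS-relative center offset, half-width) fixes the interval exactly.
    """

    name: str
    u_mixture: list[MixtureComponent] | None = None
    d_mixture: list[MixtureComponent] | None = None
    tags_per_promoter: tuple[float, float] = (60.0, 0.3)
    jitter_sd: float = 2.0
    background_fraction: float = 0.1
    motif_protection: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.background_fraction <= 1:
            raise ConfigError(f"{self.name}: background_fraction must be in [0, 1]")
        if self.jitter_sd < 0:
            raise ConfigError(f"{self.name}: jitter_sd must be >= 0")
        if self.motif_protection is None and self.tags_per_promoter[0] > 0:
            for attr in ("u_mixture", "d_mixture"):
                mix = getattr(self, attr)
                if not mix:
                    raise ConfigError(f"{self.name}: {attr} required without motif_protection")
                w = sum(c.weight for c in mix)
                if any(c.weight < 0 or c.sd < 0 for c in mix) or abs(w - 1.0) > 1e-9:
                    raise ConfigError(
                        f"{self.name}: {attr} weights must be >= 0 and sum to 1"
                    )
        elif self.motif_protection is not None and self.motif_protection[1] <= 0:
            raise ConfigError(f"{self.name}: motif half_width must be positive")

    def motif_boundaries(self) -> BoundaryPair:
        offset, hw = self.motif_protection
        u = int(np.floor(offset - hw + 0.5))
        return BoundaryPair(u=u, d=u + int(round(2 * hw)))


@dataclass
class Preset:
    """Run-level study condition: class composition, geometry per class,
    embedded site offsets per class, and silenced fraction per class."""

    name: str
    composition: dict[str, float]
    models: dict[str, str]
    sites: dict[str, list[float]] = field(default_factory=dict)
    drop: dict[str, float] = field(default_factory=dict)


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset."""

    seed: int | None = None
    preset: str | None = None
    labels: dict[str, str] = field(default_factory=dict)          # promoter -> class
    model_names: dict[str, str] = field(default_factory=dict)     # promoter -> geometry
    dropped: set[str] = field(default_factory=set)
    fragments: dict[str, np.ndarray] = field(default_factory=dict)  # (F, 2) u/d arrays
    signal_fragments: dict[str, int] = field(default_factory=dict)
    sites: list[dict] = field(default_factory=list)
    n_signal_tags: int = 0
    n_background_tags: int = 0


@dataclass
class SimConfig:
    """Settings for one synthetic run."""

    preset: str = "sigma70"
    n_promoters: int = 500
    min_spacing: int = 1000
    genome_length: int | None = None
    margin: int | None = None
    circular: bool = False
    seed: int = 0
    replicate: int = 0
    genome_name: str = "chrSim"
    embed_elements: bool = True
    composition: dict[str, float] | None = None  # overrides the preset's
    with_sequence: bool = True

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class SimResult:
    genome: GenomeModel
    promoters: list[Promoter]
    track: TagTrack
    truth: SimTruth


# ---------------------------------------------------------------------------
# preset registry
# ---------------------------------------------------------------------------


def _load_preset_file() -> dict:
    ref = resources.files("exofoot.data").joinpath("presets.yaml")
    with resources.as_file(ref) as path, open(path) as fh:
        return yaml.safe_load(fh)


def _parse_model(name: str, entry: Mapping) -> FootprintModel:
    def mix(key):
        if key not in entry:
            return None
        return [
            MixtureComponent(weight=w, mean=m, sd=s, lo=span[0], hi=span[1])
            for w, m, s, span in entry[key]
        ]

    return FootprintModel(
        name=name,
        u_mixture=mix("u_mixture"),
        d_mixture=mix("d_mixture"),
        tags_per_promoter=tuple(entry.get("tags_per_promoter", (60.0, 0.3))),
        jitter_sd=float(entry.get("jitter_sd", 2.0)),
        background_fraction=float(entry.get("background_fraction", 0.1)),
        motif_protection=(
            tuple(entry["motif_protection"]) if "motif_protection" in entry else None
        ),
    )


def default_models() -> dict[str, FootprintModel]:
    """Named footprint-geometry registry, including condition aliases."""
    raw = _load_preset_file()
    registry = {name: _parse_model(name, entry) for name, entry in raw["models"].items()}
    for alias, target in raw.get("aliases", {}).items():
        registry[alias] = dataclasses.replace(registry[target], name=alias)
    return registry


def default_presets() -> dict[str, Preset]:
    raw = _load_preset_file()
    return {
        name: Preset(
            name=name,
            composition=dict(entry["composition"]),
            models=dict(entry["models"]),
            sites={k: list(v) for k, v in entry.get("sites", {}).items()},
            drop=dict(entry.get("drop", {})),
        )
        for name, entry in raw["presets"].items()
    }


def _sigma_elements() -> tuple[dict[str, tuple[str, int]], float]:
    raw = _load_preset_file()
    elements = {k: (str(v[0]), int(v[1])) for k, v in raw["sigma_elements"].items()}
    return elements, float(raw["element_noise"])


# ---------------------------------------------------------------------------
# boundary sampling
# ---------------------------------------------------------------------------


def _draw_mixture(mixture: list[MixtureComponent], rng: np.random.Generator,
                  size: int) -> np.ndarray:
    weights = np.array([c.weight for c in mixture])
    means = np.array([c.mean for c in mixture])
    sds = np.array([c.sd for c in mixture])
    los = np.array([c.lo for c in mixture])
    his = np.array([c.hi for c in mixture])
    idx = rng.choice(len(mixture), size=size, p=weights)
    x = np.rint(rng.normal(means[idx], sds[idx]))
    # truncate to the component span by bounded resampling, then clip
    for _ in range(_MAX_RETRIES):
        bad = (x < los[idx]) | (x > his[idx])
        if not bad.any():
            break
        x[bad] = np.rint(rng.normal(means[idx][bad], sds[idx][bad]))
    x = np.clip(x, los[idx], his[idx])
    return x.astype(np.int64)


def _sample_boundaries_vec(model: FootprintModel, rng: np.random.Generator,
                           size: int) -> np.ndarray:
    """(size, 2) integer u/d pairs with u < d guaranteed."""
    if model.motif_protection is not None:
        pair = model.motif_boundaries()
        return np.tile([pair.u, pair.d], (size, 1))
    u = _draw_mixture(model.u_mixture, rng, size)
    d = _draw_mixture(model.d_mixture, rng, size)
    for _ in range(_MAX_RETRIES):
        bad = u >= d
        if not bad.any():
            return np.stack([u, d], axis=1)
        n_bad = int(bad.sum())
        u[bad] = _draw_mixture(model.u_mixture, rng, n_bad)
        d[bad] = _draw_mixture(model.d_mixture, rng, n_bad)
    raise SimulationError(
        f"model {model.name!r}: could not draw u < d in {_MAX_RETRIES} retries"
    )


def sample_boundaries(model: FootprintModel, rng: np.random.Generator) -> BoundaryPair:
    """Draw one protected-interval boundary pair from the model."""
    u, d = _sample_boundaries_vec(model, rng, 1)[0]
    return BoundaryPair(u=int(u), d=int(d))


def _fragment_count(model: FootprintModel, rng: np.random.Generator) -> int:
    mean, disp = model.tags_per_promoter
    if mean <= 0:
        return 0
    if disp <= 0:
        return int(round(mean))
    r = 1.0 / disp
    p = r / (r + mean)
    return int(rng.negative_binomial(r, p))


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------


def _effective_margin(config: SimConfig, length: int) -> int:
    if config.margin is not None:
        return config.margin
    return min(500, (length - config.n_promoters * config.min_spacing) // 2)


def _class_counts(composition: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n promoters over classes."""
    total = sum(composition.values())
    if total <= 0:
        raise ConfigError("composition weights must sum to a positive value")
    quotas = {k: v / total * n for k, v in composition.items()}
    counts = {k: int(np.floor(q)) for k, q in quotas.items()}
    short = n - sum(counts.values())
    for k in sorted(quotas, key=lambda k: quotas[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


def _embed(seq: np.ndarray, start: int, site: str) -> None:
    if start < 0 or start + len(site) > len(seq):
        raise ConfigError(
            f"embedded site [{start}, {start + len(site)}) falls outside the genome; "
            "increase margin or genome length"
        )
    seq[start : start + len(site)] = motifs.encode(site)


def build_sim_genome(
    config: SimConfig, seed: int | None = None
) -> tuple[GenomeModel, list[Promoter], SimTruth]:
    """Place promoters on a synthetic genome and embed class-specific sites.

    Promoters occupy evenly sized slots with random within-slot positions, so
    every pairwise distance is at least ``min_spacing``; strands are split
    roughly half and half.  For Crp-class promoters a 22-bp site sampled from
    the packaged Crp PWM is written into the genome sequence centered at the
    class offset (half-integer centers are exact because the site length is
    even); reverse-strand promoters receive the reverse complement.
    """
    seed = config.seed if seed is None else seed
    presets = default_presets()
    if config.preset not in presets:
        raise ConfigError(f"unknown preset {config.preset!r}; have {sorted(presets)}")
    preset = presets[config.preset]
    composition = config.composition or preset.composition
    n = config.n_promoters
    if n < 1:
        raise ConfigError("n_promoters must be >= 1")
    length = config.genome_length or n * config.min_spacing + 1000
    margin = _effective_margin(config, length)
    if margin < 0 or length - 2 * margin < n * config.min_spacing:
        raise ConfigError(
            f"cannot place {n} promoters with spacing {config.min_spacing} "
            f"on a genome of length {length}"
        )

    rng = np.random.default_rng(np.random.SeedSequence([seed, _S_GENOME]))
    slot = (length - 2 * margin) // n
    jitter_room = slot - config.min_spacing
    positions = margin + np.arange(n) * slot + (
        rng.integers(0, jitter_room + 1, size=n) if jitter_room > 0 else 0
    )
    strands = np.array(["+"] * (n - n // 2) + ["-"] * (n // 2))
    rng.shuffle(strands)

    counts = _class_counts(composition, n)
    labels = np.array([lab for lab, c in counts.items() for _ in range(c)], dtype=object)
    rng.shuffle(labels)

    promoters = [
        Promoter(id=f"p{i:04d}", tss=int(positions[i]), strand=str(strands[i]),
                 label=str(labels[i]), genes=[f"gene{i:04d}"])
        for i in range(n)
    ]

    truth = SimTruth(seed=seed, preset=preset.name,
                     labels={p.id: p.label for p in promoters},
                     model_names={p.id: preset.models.get(p.label, p.label)
                                  for p in promoters})

    genome = GenomeModel(name=config.genome_name, length=length,
                         circular=config.circular)
    if config.with_sequence:
        seq = rng.integers(0, 4, size=length).astype(np.uint8)
        pwm = motifs.load_crp_pwm()
        elements, noise = _sigma_elements()
        for p in promoters:
            if config.embed_elements:
                for el_seq, el_start in elements.values():
                    noisy = _mutate(el_seq, noise, rng)
                    if p.strand == "+":
                        _embed(seq, p.tss + el_start, noisy)
                    else:
                        from .core import revcomp

                        _embed(seq, p.tss - (el_start + len(noisy) - 1), revcomp(noisy))
            for offset in preset.sites.get(p.label, []):
                site = pwm.sample(rng)
                half = (pwm.length - 1) / 2.0
                if p.strand == "+":
                    start = int(p.tss + offset - half)
                    _embed(seq, start, site)
                    center = start + half
                else:
                    from .core import revcomp

                    start = int(p.tss - offset - half)
                    _embed(seq, start, revcomp(site))
                    center = start + half
                truth.sites.append({
                    "promoter_id": p.id, "offset": float(offset),
                    "center": float(center), "strand": p.strand, "sequence": site,
                })
        genome.sequence = "".join("ACGT"[c] for c in seq)
    return genome, promoters, truth


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    for j in range(len(out)):
        if rng.random() < rate:
            out[j] = "ACGT"[rng.integers(0, 4)]
    return "".join(out)


# ---------------------------------------------------------------------------
# tag emission
# ---------------------------------------------------------------------------


def emit_tags(
    genome: GenomeModel,
    promoters: list[Promoter],
    models: Mapping[str, FootprintModel],
    seed: int,
    replicate: int = 0,
) -> tuple[TagTrack, SimTruth]:
    """Emit per-strand 5' tag counts for every promoter plus uniform background.

    Each fragment contributes exactly two tags.  With probability
    ``background_fraction`` a fragment is rerouted to background: its two tags
    land at uniform positions on uniform strands.  Otherwise the boundary
    offsets (plus integer-rounded Gaussian jitter) are mapped through the
    promoter strand and the leftmost genomic boundary receives a
    forward-strand tag, the rightmost a reverse-strand tag.
    """
    track = TagTrack.zeros(genome)
    truth = SimTruth(seed=seed)
    L = genome.length
    for i, prom in enumerate(promoters):
        if prom.label not in models:
            raise DataError(f"no footprint model for label {prom.label!r}")
        model = models[prom.label]
        rng_frag = np.random.default_rng(np.random.SeedSequence([seed, _S_FRAG, i]))
        n_frag = _fragment_count(model, rng_frag)
        pairs = (_sample_boundaries_vec(model, rng_frag, n_frag)
                 if n_frag else np.empty((0, 2), dtype=np.int64))
        truth.fragments[prom.id] = pairs
        truth.labels[prom.id] = prom.label
        truth.model_names[prom.id] = model.name
        if n_frag == 0:
            truth.signal_fragments[prom.id] = 0
            continue

        rng_tag = np.random.default_rng(
            np.random.SeedSequence([seed, _S_TAG, i, replicate])
        )
        is_bg = rng_tag.random(n_frag) < model.background_fraction
        jit = np.rint(rng_tag.normal(0.0, model.jitter_sd, size=(n_frag, 2))).astype(
            np.int64
        )
        off = pairs + jit
        sign = 1 if prom.strand == "+" else -1
        g = prom.tss + sign * off
        left = g.min(axis=1)
        right = g.max(axis=1)
        n_bg = int(is_bg.sum())
        if n_bg:
            bg_pos = rng_tag.integers(0, L, size=2 * n_bg)
            bg_fwd = rng_tag.random(2 * n_bg) < 0.5
            np.add.at(track.forward, bg_pos[bg_fwd], 1)
            np.add.at(track.reverse, bg_pos[~bg_fwd], 1)
        sig = ~is_bg
        if genome.circular:
            left, right = left % L, right % L
        else:
            left = np.clip(left, 0, L - 1)
            right = np.clip(right, 0, L - 1)
        np.add.at(track.forward, left[sig], 1)
        np.add.at(track.reverse, right[sig], 1)
        truth.signal_fragments[prom.id] = int(sig.sum())
        truth.n_signal_tags += 2 * int(sig.sum())
        truth.n_background_tags += 2 * n_bg
    return track, truth


# ---------------------------------------------------------------------------
# the full run
# ---------------------------------------------------------------------------


def _apply_drops(
    promoters: list[Promoter], preset: Preset, seed: int
) -> tuple[list[Promoter], set[str]]:
    """Relabel the silenced fraction of each class to the 'silenced' model."""
    if not preset.drop:
        return promoters, set()
    rng = np.random.default_rng(np.random.SeedSequence([seed, _S_DROP]))
    dropped: set[str] = set()
    for label, fraction in preset.drop.items():
        idx = [i for i, p in enumerate(promoters) if p.label == label]
        k = int(round(fraction * len(idx)))
        for i in rng.choice(len(idx), size=k, replace=False):
            dropped.add(promoters[idx[i]].id)
    out = [
        dataclasses.replace(p, label="silenced") if p.id in dropped else p
        for p in promoters
    ]
    return out, dropped


def simulate(config: SimConfig) -> SimResult:
    """Genome + promoters + tags for one preset run, with merged truth."""
    genome, promoters, truth = build_sim_genome(config)
    preset = default_presets()[config.preset]
    effective, dropped = _apply_drops(promoters, preset, config.seed)
    registry = default_models()
    label_models = {lab: registry[mod] for lab, mod in preset.models.items()}
    label_models["silenced"] = registry["silenced"]
    track, tag_truth = emit_tags(
        genome, effective, label_models, seed=config.seed, replicate=config.replicate
    )
    truth.dropped = dropped
    truth.fragments = tag_truth.fragments
    truth.signal_fragments = tag_truth.signal_fragments
    truth.n_signal_tags = tag_truth.n_signal_tags
    truth.n_background_tags = tag_truth.n_background_tags
    return SimResult(genome=genome, promoters=promoters, track=track, truth=truth)
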