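"""Seeded generator of synthetic leaf-series landmark datasets.

The generator emulates the statistical structure of vining-plant leaf
collections: several species, several vines per species, and an ordered
node series per vine, with

* a shared smooth heteroblastic shape trajectory (a fixed quadratic
  displacement field whose strength grows from tip to base),
* ontogenetic allometric contraction near the growing tip (young leaves
  smaller and relatively elongated),
* a fixed random per-species offset field, encoding species-to-species
  shape differences as departures from one shared developmental program
  (the generator's null structure),
* optionally, for designated "divergent" species, an extra mid-series
  displacement that switches on smoothly inside a relative-node band and
  vanishes at both band edges -- the branch-and-rejoin ("reverse
  hourglass") signature, and
* i.i.d. Gaussian landmark noise.

Everything is reproducible from the config seed; species offset fields
are seeded from (seed, species label), so adding vines or nodes never
perturbs the species effects.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import yaml

from leaftda.landmark_io import Leaf, LeafDataset, LandmarkScheme, builtin_scheme

__all__ = ["SyntheticConfig", "base_shape", "deform", "generate", "species_offset_field"]


def _template_curve(t: np.ndarray) -> np.ndarray:
    """Analytic lobed leaf-outline template, evaluated at curve parameter t.

    A closed polar curve rho(theta) = 1 + 0.22 cos(2 theta) + 0.10 cos(5 theta)
    with theta = 2 pi t - pi/2, so t = 0 is the proximal (petiolar) end.
    The two harmonics give a mildly bilobed outline with finer marginal
    structure, enough shape for landmarks to be mutually informative.
    """
    t = np.asarray(t, dtype=float)
    theta = 2.0 * np.pi * t - np.pi / 2.0
    rho = 1.0 + 0.22 * np.cos(2.0 * theta) + 0.10 * np.cos(5.0 * theta)
    return np.stack([rho * np.cos(theta), rho * np.sin(theta)], axis=-1)


def base_shape(n_landmarks: int, normalize: bool = True) -> np.ndarray:
    """Sample the leaf template at n equally spaced curve parameters.

    With ``normalize`` (default), the sampled polygon is centered at the
    origin and scaled to unit centroid size. The raw samples (``normalize
    = False``) lie exactly on the analytic template curve, so different
    n share one underlying outline.
    """
    if n_landmarks < 3:
        raise ValueError("need at least 3 landmarks")
    pts = _template_curve(np.arange(n_landmarks) / n_landmarks)
    if not normalize:
        return pts
    pts = pts - pts.mean(axis=0)
    return pts / np.sqrt((pts**2).sum())


@dataclass(frozen=True)
class SyntheticConfig:
    """All parameters of the generative leaf-series model.

    Amplitudes are in units of the (unit-centroid-size) base shape;
    ``divergence_band`` is a relative-node window [lo, hi] within [0, 1]
    (0 = growing tip) where divergent species deviate from the shared
    trajectory.
    """

    n_species: int = 6
    vines_per_species: int = 5
    nodes_per_vine: int = 12
    nodes_jitter: int = 3
    n_landmarks: int = 15
    heteroblasty_amplitude: float = 0.5
    ontogeny_amplitude: float = 0.4
    species_effect_sd: float = 0.03
    lineage_effect_sd: float = 0.0
    divergent_species: frozenset[str] = frozenset()
    divergence_band: tuple[float, float] = (0.3, 0.7)
    divergence_amplitude: float = 0.25
    noise_sd: float = 0.02
    seed: int = 0
    species_labels: tuple[str, ...] | None = None
    group_prefix: str = "sp"

    def __post_init__(self) -> None:
        for name in ("n_species", "vines_per_species", "nodes_per_vine"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_landmarks < 3:
            raise ValueError("n_landmarks must be >= 3")
        if self.nodes_jitter < 0 or self.nodes_jitter >= self.nodes_per_vine:
            raise ValueError("nodes_jitter must be in [0, nodes_per_vine)")
        for name in (
            "heteroblasty_amplitude",
            "ontogeny_amplitude",
            "species_effect_sd",
            "lineage_effect_sd",
            "divergence_amplitude",
            "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        object.__setattr__(self, "divergence_band", tuple(self.divergence_band))
        lo, hi = self.divergence_band
        if not 0.0 <= lo < hi <= 1.0:
            raise ValueError(f"divergence_band must satisfy 0 <= lo < hi <= 1, got {self.divergence_band}")
        object.__setattr__(self, "divergent_species", frozenset(self.divergent_species))
        if self.species_labels is not None:
            object.__setattr__(self, "species_labels", tuple(self.species_labels))
            if len(self.species_labels) != self.n_species:
                raise ValueError("species_labels length must equal n_species")

    def labels(self) -> tuple[str, ...]:
        if self.species_labels is not None:
            return tuple(self.species_labels)
        return tuple(f"{self.group_prefix}{i:02d}" for i in range(self.n_species))

    def to_yaml(self) -> str:
        doc = {
            "n_species": self.n_species,
            "vines_per_species": self.vines_per_species,
            "nodes_per_vine": self.nodes_per_vine,
            "nodes_jitter": self.nodes_jitter,
            "n_landmarks": self.n_landmarks,
            "heteroblasty_amplitude": self.heteroblasty_amplitude,
            "ontogeny_amplitude": self.ontogeny_amplitude,
            "species_effect_sd": self.species_effect_sd,
            "lineage_effect_sd": self.lineage_effect_sd,
            "divergent_species": sorted(self.divergent_species),
            "divergence_band": list(self.divergence_band),
            "divergence_amplitude": self.divergence_amplitude,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "species_labels": list(self.species_labels) if self.species_labels else None,
            "group_prefix": self.group_prefix,
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SyntheticConfig":
        doc = yaml.safe_load(text)
        if doc.get("divergence_band") is not None:
            doc["divergence_band"] = tuple(doc["divergence_band"])
        if doc.get("divergent_species") is not None:
            doc["divergent_species"] = frozenset(doc["divergent_species"])
        if doc.get("species_labels") is not None:
            doc["species_labels"] = tuple(doc["species_labels"])
        return cls(**doc)


def species_offset_field(cfg: SyntheticConfig, species: str) -> np.ndarray:
    """Fixed per-species landmark offset field, (n, 2).

    Seeded from (cfg.seed, crc32(species label)) so it is stable across
    runs and independent of how many vines or nodes are generated.
    """
    rng = np.random.default_rng([cfg.seed % (2**31), zlib.crc32(species.encode())])
    return rng.normal(0.0, cfg.species_effect_sd, size=(cfg.n_landmarks, 2))


def lineage_offset_field(cfg: SyntheticConfig) -> np.ndarray:
    """Fixed lineage-level (genus) offset field shared by every species.

    Represents deep between-lineage divergence of the leaf bauplan, on top
    of which species offsets and the shared developmental trajectory act.
    Seeded from (cfg.seed, "lineage:" + group_prefix).
    """
    rng = np.random.default_rng(
        [cfg.seed % (2**31), zlib.crc32(f"lineage:{cfg.group_prefix}".encode())]
    )
    return rng.normal(0.0, cfg.lineage_effect_sd, size=(cfg.n_landmarks, 2))


def _bump(r: float, lo: float, hi: float) -> float:
    """Smooth bump on [lo, hi], vanishing at both edges: sin^2 profile."""
    if r <= lo or r >= hi:
        return 0.0
    return float(np.sin(np.pi * (r - lo) / (hi - lo)) ** 2)


def deform(
    shape: np.ndarray,
    r: float,
    cfg: SyntheticConfig,
    species: str,
) -> np.ndarray:
    """Deterministic deformation of the base shape at relative node r.

    Applies, in order: the shared heteroblastic displacement field (scaled
    by amplitude * r), ontogenetic allometric contraction and elongation
    (scaled by amplitude * (1 - r), strongest at the tip), the fixed
    species offset field, and -- for divergent species with r inside the
    divergence band -- the extra divergence field scaled by a smooth bump
    that vanishes at the band edges. Noise is *not* added here.
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"r must be in [0, 1], got {r}")
    p = np.asarray(shape, dtype=float).copy()
    x, y = p[:, 0], p[:, 1]

    # (i) shared heteroblastic field: smooth quadratic displacement that
    # deepens the lobes and shears the blade as leaves mature toward the base
    h = cfg.heteroblasty_amplitude * r
    dx = 0.5 * x * y
    dy = 0.4 * (y**2 - x**2)
    p = p + h * np.stack([dx, dy], axis=1)

    # (ii) ontogenetic allometry: tip leaves smaller and relatively elongated
    o = cfg.ontogeny_amplitude * (1.0 - r)
    scale = 1.0 - 0.5 * o
    elong = 1.0 + 0.7 * o
    p = p * scale
    p[:, 1] *= elong

    # (iii) fixed lineage and species offset fields
    if cfg.lineage_effect_sd > 0:
        p = p + lineage_offset_field(cfg)
    p = p + species_offset_field(cfg, species)

    # (iv) mid-series divergence for designated species
    if species in cfg.divergent_species and cfg.divergence_amplitude > 0:
        w = _bump(r, *cfg.divergence_band)
        if w > 0.0:
            # high-frequency relative to the blade so the deviation is
            # non-affine in the flattened vector (the correlation distance
            # is blind to affine displacement components)
            gx = 0.8 * np.sin(9.0 * p[:, 1] + 0.7)
            gy = 0.8 * np.cos(8.0 * p[:, 0] - 0.4)
            p = p + cfg.divergence_amplitude * w * np.stack([gx, gy], axis=1)
    return p


def generate(cfg: SyntheticConfig) -> LeafDataset:
    """Generate a full synthetic leaf dataset under the config.

    Layout mirrors the field collections: for each species, each vine
    carries nodes 1..N counted from the growing tip, with N drawn
    uniformly from nodes_per_vine +- nodes_jitter (real vines differ in
    length, which also makes the relative-node lens dense rather than a
    coarse common grid); the deformation parameter of node k is
    r = (k - 1) / (N - 1). Vine lengths and per-leaf Gaussian noise are
    drawn in a fixed nested order (species sorted by label, then vine,
    then node) from a generator seeded with cfg.seed.
    """
    base = base_shape(cfg.n_landmarks)
    rng = np.random.default_rng(cfg.seed % (2**31))
    leaves = []
    for species in sorted(cfg.labels()):
        for v in range(cfg.vines_per_species):
            vine_id = f"{species}_v{v}"
            if cfg.nodes_jitter:
                n = int(
                    rng.integers(
                        cfg.nodes_per_vine - cfg.nodes_jitter,
                        cfg.nodes_per_vine + cfg.nodes_jitter + 1,
                    )
                )
            else:
                n = cfg.nodes_per_vine
            for k in range(1, n + 1):
                r = 0.0 if n == 1 else (k - 1) / (n - 1)
                lm = deform(base, r, cfg, species)
                if cfg.noise_sd > 0:
                    lm = lm + rng.normal(0.0, cfg.noise_sd, size=lm.shape)
                leaves.append(
                    Leaf(
                        leaf_id=f"{vine_id}_n{k:02d}",
                        group_label=species,
                        vine_id=vine_id,
                        node_index=k,
                        landmarks=lm,
                    )
                )
    if cfg.n_landmarks == 15:
        scheme = builtin_scheme("grapevine")
    elif cfg.n_landmarks == 21:
        scheme = builtin_scheme("maracuya")
    else:
        scheme = LandmarkScheme(
            f"synthetic{cfg.n_landmarks}",
            cfg.n_landmarks,
            tuple(f"lm{i:02d}" for i in range(cfg.n_landmarks)),
            axis_indices=(0, cfg.n_landmarks - 1),
        )
    return LeafDataset(
        scheme,
        tuple(leaves),
        provenance=f"synthetic(seed={cfg.seed},n_species={cfg.n_species})",
    )
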