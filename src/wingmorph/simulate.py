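"""Synthetic landmark and sequence data with study-like structure.

The generator emulates the sampling design of a highland Africanization
survey: four pure-subspecies reference panels (50 wings each), fifteen
apiaries of five colonies x ten wings (750 study wings) whose shapes are
mixtures of the reference means (a hybrid mixing weight lambda leaning
toward the *A. m. scutellata*-like mean produces the dominant Africanized
morphotype), apiary altitudes tiling 2600-3274 m a.s.l., and a negative
altitude-centroid-size correlation (default rho = -0.32).  An optional
placebo outgroup sits far outside the *A. mellifera* cluster, mimicking a
stingless-bee (*Tetragonisca angustula*) control.

Shapes are built as a common base wing outline plus per-group tangent
offsets and isotropic Gaussian tangent noise; raw coordinates are emitted
with random rotation, translation and scale so the pipeline must genuinely
undo them.  Centroid size follows CS = beta0 + beta1 * altitude + eps,
calibrated so the population altitude-size correlation equals rho.

Sequence companion: a synthetic haplotype panel (mutually divergent
variants of a random base sequence, named after real African-lineage
haplotypes) and per-query random substitutions at a chosen rate, with the
true haplotype kept for recovery scoring.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .gpa import _center_scale
from .haplotype import SequenceRecord, PanelEntry
from .tps import Dataset, LandmarkConfiguration, write_tps

__all__ = [
    "SimulationConfig",
    "make_base_shape",
    "make_reference_means",
    "sample_population",
    "simulate_study",
    "StudySimulation",
    "make_haplotype_panel",
    "mutate_sequences",
    "write_study",
]

REFERENCE_NAMES = (
    "A. m. carnica",
    "A. m. ligustica",
    "A. m. mellifera",
    "A. m. scutellata",
)

HAPLOTYPE_NAMES = ("A1", "A1e", "A1q", "A26", "A26a", "A26c", "A30")


@dataclass
class SimulationConfig:
    """Study-shaped simulation parameters.

    Defaults reproduce the survey design: 19 landmarks, 4 balanced
    reference panels of 50, 15 apiaries x 5 colonies x 10 wings, hybrid
    mixing weight 0.9 toward the scutellata-like mean, altitude range
    2600-3274 m with target size correlation -0.32.
    """

    k: int = 19
    reference_names: tuple[str, ...] = REFERENCE_NAMES
    n_per_reference: int = 50
    n_apiaries: int = 15
    colonies_per_apiary: int = 5
    wings_per_colony: int = 10
    separation: float = 0.06       # tangent-norm offset between reference means
    sigma_w: float = 0.015         # within-group tangent noise SD per coordinate
    hybrid_lambda: float = 0.9     # mixing weight toward the scutellata-like mean
    altitude_range: tuple[float, float] = (2600.0, 3274.0)
    rho: float = -0.32             # target altitude-centroid-size correlation
    cs_mean: float = 7.5           # mean centroid size, image units
    cs_sd: float = 0.35            # total SD of centroid size
    include_placebo: bool = True
    placebo_name: str = "placebo"
    n_placebo: int = 10
    placebo_separation_factor: float = 10.0
    nuisance: bool = True          # random rotation/translation/scale on output
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 3:
            raise ConfigError("k must be >= 3")
        if not (0 <= self.hybrid_lambda <= 1):
            raise ConfigError("hybrid_lambda must be in [0, 1]")
        if not (-1 < self.rho < 1):
            raise ConfigError("rho must be in (-1, 1)")
        if self.sigma_w <= 0:
            raise ConfigError("sigma_w must be > 0")
        if min(self.n_per_reference, self.n_apiaries,
               self.colonies_per_apiary, self.wings_per_colony) < 1:
            raise ConfigError("all sample counts must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["reference_names"] = list(self.reference_names)
        d["altitude_range"] = list(self.altitude_range)
        return d


def make_base_shape(k: int) -> np.ndarray:
    """Deterministic non-degenerate base wing outline: a ring polygon with
    a fixed low-order radial perturbation, centred with unit centroid
    size."""
    theta = 2 * np.pi * np.arange(k) / k
    radius = 1.0 + 0.18 * np.sin(3 * theta + 0.7) + 0.10 * np.cos(5 * theta)
    coords = np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])
    return _center_scale(coords)


def _nuisance_basis(base_flat: np.ndarray, k: int) -> np.ndarray:
    """Orthonormal basis of the directions GPA removes at the base shape:
    x-translation, y-translation, scaling (along the shape vector) and
    infinitesimal rotation."""
    tx = np.tile([1.0, 0.0], k)
    ty = np.tile([0.0, 1.0], k)
    sc = base_flat.copy()
    xy = base_flat.reshape(k, 2)
    rot = np.column_stack([-xy[:, 1], xy[:, 0]]).reshape(-1)
    basis = np.stack([tx, ty, sc, rot]).T  # (2k, 4)
    q, _ = np.linalg.qr(basis)
    return q


def _project_tangent(v: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Remove the translation/scale/rotation components from a 2k vector."""
    return v - q @ (q.T @ v)


def make_reference_means(
    k: int,
    separation: float,
    seed: Optional[int] = None,
    n_groups: int = 4,
    names: Optional[Sequence[str]] = None,
) -> dict[str, np.ndarray]:
    """Per-group mean shapes: the base shape plus random tangent offsets of
    norm = separation (orthogonal to the similarity-transform directions),
    re-centred to unit centroid size.  separation = 0 collapses all means
    onto the base shape."""
    if k < 3:
        raise ConfigError("k must be >= 3")
    if separation < 0:
        raise ConfigError("separation must be >= 0")
    if names is None:
        names = [f"group{i + 1}" for i in range(n_groups)]
    rng = np.random.default_rng(seed)
    base = make_base_shape(k)
    base_flat = base.reshape(-1)
    q = _nuisance_basis(base_flat, k)
    means: dict[str, np.ndarray] = {}
    for name in names:
        offset = _project_tangent(rng.standard_normal(2 * k), q)
        norm = np.linalg.norm(offset)
        if norm > 0 and separation > 0:
            offset *= separation / norm
        else:
            offset = np.zeros(2 * k)
        means[name] = _center_scale((base_flat + offset).reshape(k, 2))
    return means


def _size_model(config: SimulationConfig) -> tuple[float, float, float]:
    """(beta0, beta1, sigma_eps) such that for altitude uniform over the
    study range, corr(altitude, CS) = rho and SD(CS) = cs_sd."""
    lo, hi = config.altitude_range
    sigma_alt = (hi - lo) / np.sqrt(12.0)
    beta1 = config.rho * config.cs_sd / sigma_alt
    sigma_eps = config.cs_sd * np.sqrt(1 - config.rho**2)
    beta0 = config.cs_mean - beta1 * (lo + hi) / 2.0
    return beta0, beta1, sigma_eps


def _emit_specimens(
    ids, shapes_flat, sizes, rng, nuisance: bool, metadata_rows
) -> list[LandmarkConfiguration]:
    configs = []
    for sid, flat, cs, md in zip(ids, shapes_flat, sizes, metadata_rows):
        # the specimen's centroid size IS the scale nuisance: GPA must
        # undo it, and it carries the altitude-size signal
        shape = _center_scale(flat.reshape(-1, 2)) * cs
        if nuisance:
            theta = rng.uniform(0, 2 * np.pi)
            c, s = np.cos(theta), np.sin(theta)
            shape = shape @ np.array([[c, s], [-s, c]])
            shape = shape + rng.uniform(-50, 50, size=2)
        configs.append(LandmarkConfiguration(sid, shape, md))
    return configs


def sample_population(
    config: SimulationConfig,
    name: str,
    n: int,
    weights: dict[str, float],
    altitude_range: tuple[float, float],
    means: dict[str, np.ndarray],
    rng: np.random.Generator,
    group_label: Optional[str] = None,
    apiary: Optional[str] = None,
    id_prefix: Optional[str] = None,
) -> list[LandmarkConfiguration]:
    """Draw n specimens for one population as a mixture of reference mean
    shapes plus isotropic tangent noise, with altitudes uniform in the
    population's range and centroid sizes from the calibrated size model."""
    wsum = sum(weights.values())
    if not np.isclose(wsum, 1.0, atol=1e-9):
        raise ConfigError(f"mixing weights for {name!r} sum to {wsum}, not 1")
    k = config.k
    mean_flat = sum(
        w * means[g].reshape(-1) for g, w in weights.items()
    )
    q = _nuisance_basis(make_base_shape(k).reshape(-1), k)
    beta0, beta1, sigma_eps = _size_model(config)

    altitudes = np.round(rng.uniform(*altitude_range, size=n)).astype(int)
    sizes = beta0 + beta1 * altitudes + rng.normal(0, sigma_eps, size=n)
    sizes = np.clip(sizes, 0.05 * config.cs_mean, None)

    noise = rng.normal(0, config.sigma_w, size=(n, 2 * k))
    noise = noise - (noise @ q) @ q.T  # keep noise in the tangent directions
    shapes_flat = mean_flat[None, :] + noise

    prefix = id_prefix or name
    ids = [f"{prefix}-{i + 1:03d}" for i in range(n)]
    metadata_rows = []
    per_colony = config.wings_per_colony
    for i in range(n):
        md = {
            "altitude_masl": float(altitudes[i]),
            "group_label": group_label,
            "apiary": apiary,
        }
        if apiary is not None:
            md["colony"] = f"{apiary}-C{i // per_colony + 1}"
        metadata_rows.append(md)
    return _emit_specimens(ids, shapes_flat, sizes, rng, config.nuisance,
                           metadata_rows)


@dataclass
class StudySimulation:
    """A full study-shaped simulated dataset plus its generating config."""

    dataset: Dataset
    config: SimulationConfig
    reference_means: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    @property
    def metadata(self) -> pd.DataFrame:
        return self.dataset.metadata_frame()


def simulate_study(config: Optional[SimulationConfig] = None) -> StudySimulation:
    """Generate the complete study-shaped dataset: reference panels,
    apiary populations (hybrids leaning toward the scutellata-like mean)
    and the optional placebo outgroup, all with nuisance transforms."""
    if config is None:
        config = SimulationConfig()
    rng = np.random.default_rng(config.seed)
    names = list(config.reference_names)
    means = make_reference_means(
        config.k, config.separation,
        seed=rng.integers(2**31), names=names,
    )
    scut = names[-1]  # scutellata-like reference is the last name
    configs: list[LandmarkConfiguration] = []

    # reference panels: pure subspecies, one mean each
    for name in names:
        configs.extend(
            sample_population(
                config, name, config.n_per_reference,
                weights={name: 1.0},
                altitude_range=config.altitude_range,
                means=means, rng=rng, group_label=name,
                id_prefix=f"ref-{name.split('.')[-1].strip()}",
            )
        )

    # apiary populations: hybrid mixture leaning toward scutellata
    lam = config.hybrid_lambda
    others = [g for g in names if g != scut]
    weights = {scut: lam}
    for g in others:
        weights[g] = (1 - lam) / len(others)
    lo, hi = config.altitude_range
    edges = np.linspace(lo, hi, config.n_apiaries + 1)
    n_per_apiary = config.colonies_per_apiary * config.wings_per_colony
    for a in range(config.n_apiaries):
        apiary = f"A{a + 1}"
        configs.extend(
            sample_population(
                config, apiary, n_per_apiary, weights=weights,
                altitude_range=(edges[a], edges[a + 1]),
                means=means, rng=rng, group_label=None, apiary=apiary,
                id_prefix=apiary,
            )
        )

    # placebo outgroup far outside the A. mellifera cluster
    if config.include_placebo:
        placebo_means = make_reference_means(
            config.k,
            config.separation * config.placebo_separation_factor,
            seed=rng.integers(2**31), names=[config.placebo_name],
        )
        means = {**means, **placebo_means}
        configs.extend(
            sample_population(
                config, config.placebo_name, config.n_placebo,
                weights={config.placebo_name: 1.0},
                altitude_range=config.altitude_range,
                means=means, rng=rng, group_label=config.placebo_name,
                id_prefix="placebo",
            )
        )

    return StudySimulation(dataset=Dataset(configs), config=config,
                           reference_means=means)


def write_study(sim: StudySimulation, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write a simulation as TPS + metadata CSV + YAML config sidecar;
    returns the paths."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    tps_path = os.path.join(out_dir, "landmarks.tps")
    meta_path = os.path.join(out_dir, "metadata.csv")
    cfg_path = os.path.join(out_dir, "simulation.yaml")
    write_tps(sim.dataset, tps_path)
    meta = sim.metadata.reset_index()
    meta.to_csv(meta_path, index=False)
    with open(cfg_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(sim.config.to_dict(), fh, sort_keys=False)
    return {"tps": tps_path, "metadata": meta_path, "config": cfg_path}


# ---------------------------------------------------------------------------
# sequence companion


def make_haplotype_panel(
    n_haplotypes: int = 7,
    length: int = 560,
    divergence: float = 0.05,
    seed: Optional[int] = None,
    lineage: str = "A",
) -> list[PanelEntry]:
    """Synthetic haplotype panel: each haplotype is the random base
    sequence mutated at `divergence` per base, so haplotypes are mutually
    ~2x divergence apart.  Names follow African-lineage conventions."""
    if not (0 < divergence <= 0.2):
        raise ConfigError("divergence must be in (0, 0.2]")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    base_seq = rng.choice(bases, size=length)
    names = list(HAPLOTYPE_NAMES)
    while len(names) < n_haplotypes:
        names.append(f"A{len(names) + 30}")
    entries = []
    for name in names[:n_haplotypes]:
        seq = _mutate(base_seq.copy(), divergence, rng, bases)
        entries.append(
            PanelEntry(
                record=SequenceRecord(name, "".join(seq)),
                haplotype=name, lineage=lineage,
            )
        )
    return entries


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator,
            bases: np.ndarray) -> np.ndarray:
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        choices = bases[bases != seq[i]]
        seq[i] = rng.choice(choices)
    return seq


def mutate_sequences(
    panel: Sequence[PanelEntry],
    rate: float,
    n_per_haplotype: int,
    seed: Optional[int] = None,
) -> list[tuple[SequenceRecord, str]]:
    """Queries derived from panel members by i.i.d. substitutions at the
    given per-base rate; returns (query, true haplotype) pairs."""
    if not (0 <= rate <= 0.2):
        raise ConfigError("rate must be in [0, 0.2]")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    out = []
    for entry in panel:
        src = np.array(list(entry.record.seq))
        for j in range(n_per_haplotype):
            mutated = _mutate(src.copy(), rate, rng, bases)
            rec = SequenceRecord(f"{entry.haplotype}-q{j + 1}", "".join(mutated))
            out.append((rec, entry.haplotype))
    return out
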