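"""The LALI-type -> phenotype (L->P) map.

A *LALI-type* is the full parameter set of one pattern mechanism — the
stand-in for genotype and environment taken together.  Because the
simulators are stochastic (random initial conditions model developmental
noise), a single LALI-type maps to a distribution of phenotypes, its
*phenotype cloud*; conversely a given phenotype can be produced by many
LALI-types, its *neutral region*.  This module implements:

* Monte-Carlo phenotype clouds with deterministic child seeding,
* r% clouds (the r% of members nearest the cloud center) and the
  containment test they induce,
* neutral-region scans of a 2-D slice of LALI-space,
* best-match search (closest simulated pattern to a target phenotype),
* the 0-4 relatedness score between phenotypes under both models,
* the LALI-grid -> phenotype map with its area-bias summary.

Distances in phenotype space are unweighted Euclidean on [FA, EE]; both
coordinates are dimensionless and bounded by [0, 1].  Configurable
weights are provided for sensitivity analyses.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import simulators as sim
from .morphometrics import (
    BinaryPattern,
    EmptyPatternError,
    Phenotype,
    clean_pattern,
    cut_scaled_disk,
    measure_phenotype,
)

__all__ = [
    "LALIType",
    "DomainSpec",
    "PhenotypeCloud",
    "NeutralRegion",
    "ParamGrid",
    "CloudCache",
    "simulate_pattern",
    "generate_cloud",
    "cloud_center",
    "r_cloud",
    "contains",
    "neutral_region_scan",
    "best_match",
    "relatedness",
    "relatedness_matrix",
    "grid_phenotype_map",
]

logger = logging.getLogger(__name__)

_LINEAR_VARIED = ("f_u", "T_rel")
_FHN_VARIED = ("rho", "T_rel")


@dataclass(frozen=True)
class LALIType:
    """One point in LALI-space: a model identity plus its parameters.

    ``coords`` holds the two coordinates varied in scans — (f_u, T_rel)
    for the linear model, (rho, T_rel) for FHN, where T_rel is the
    binarization threshold relative to the mean shifted morphogen.
    ``fixed`` overrides any other simulator parameter (grid_n, n_steps,
    t_end, the linear kinetic constants, ...); unspecified parameters
    take the model defaults.
    """

    model: str  # "linear" | "fhn"
    coords: tuple[tuple[str, float], ...]
    fixed: tuple[tuple[str, float], ...] = ()

    def __init__(self, model, coords=None, fixed=None, **kw):
        if model not in ("linear", "fhn"):
            raise ValueError(f"model must be 'linear' or 'fhn': got {model!r}")
        coords = dict(coords or {})
        coords.update({k: kw[k] for k in list(kw) if k in _LINEAR_VARIED + _FHN_VARIED})
        varied = _LINEAR_VARIED if model == "linear" else _FHN_VARIED
        unknown = set(coords) - set(varied)
        if unknown:
            raise ValueError(f"unknown varied coordinate(s) {sorted(unknown)} for model {model!r}")
        if "T_rel" not in coords:
            raise ValueError("coords must include the threshold T_rel")
        object.__setattr__(self, "model", model)
        object.__setattr__(self, "coords", tuple(sorted(coords.items())))
        object.__setattr__(self, "fixed", tuple(sorted(dict(fixed or {}).items())))

    @property
    def T_rel(self) -> float:
        return dict(self.coords)["T_rel"]

    def sim_params(self, seed) -> sim.LinearTuringParams | sim.FHNParams:
        kw = {k: v for k, v in self.coords if k != "T_rel"}
        kw.update(dict(self.fixed))
        kw["seed"] = seed
        cls = sim.LinearTuringParams if self.model == "linear" else sim.FHNParams
        return cls(**kw)


@dataclass(frozen=True)
class DomainSpec:
    """How much of the simulated domain enters the phenotype.

    ``None`` (use the full domain) or a disk cut at a matched physical
    scale: the simulated pattern's mean spot size is pinned to
    ``target_spot_size_cm`` and a disk of ``target_radius_cm`` is cut at
    a random position, emulating a finite field of view.
    """

    target_spot_size_cm: float
    target_radius_cm: float


def _child_seed(master_seed: int, index: int) -> np.random.SeedSequence:
    """Deterministic per-simulation seed: counter-based spawn of the master."""
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))


def simulate_pattern(
    lali_type: LALIType,
    seed,
    domain_spec: DomainSpec | None = None,
    *,
    min_spot_area: int = 10,
) -> BinaryPattern:
    """Run one simulation of a LALI-type and binarize it.

    Stray components below ``min_spot_area`` are removed; interior holes
    are kept (ring-shaped spots are a genuine output of the FHN model,
    not threshold noise).  With a ``domain_spec``, a scale-matched disk
    is cut using a sub-seed derived from ``seed``.
    """
    seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    sim_seq, cut_seq = seq.spawn(2)
    params = lali_type.sim_params(sim_seq)
    fld = (
        sim.simulate_linear(params)
        if lali_type.model == "linear"
        else sim.simulate_fhn(params)
    )
    pat = sim.binarize_field(fld, lali_type.T_rel)
    pat = clean_pattern(pat, min_spot_area=min_spot_area, fill_holes=False)
    if domain_spec is not None:
        pat = cut_scaled_disk(
            pat,
            domain_spec.target_spot_size_cm,
            domain_spec.target_radius_cm,
            seed=cut_seq,
        )
    return pat


# --------------------------------------------------------------------------
# phenotype clouds
# --------------------------------------------------------------------------

@dataclass
class PhenotypeCloud:
    """Monte-Carlo distribution of phenotypes for one LALI-type.

    ``phenotypes`` is an (n, 2) array of [FA, EE] rows.  ``center`` is
    the componentwise mean — the 'typical' phenotype of the LALI-type —
    and ``center_distances`` the sorted distances of members from it.
    """

    lali_type: LALIType | None
    phenotypes: np.ndarray
    master_seed: int | None = None
    domain_spec: DomainSpec | None = None
    n_excluded: int = 0
    weights: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.phenotypes = np.atleast_2d(np.asarray(self.phenotypes, dtype=float))
        if self.phenotypes.shape[0] < 1 or self.phenotypes.shape[1] != 2:
            raise ValueError("phenotypes must be a nonempty (n, 2) array")

    @property
    def n(self) -> int:
        return self.phenotypes.shape[0]

    @property
    def center(self) -> np.ndarray:
        return self.phenotypes.mean(axis=0)

    def distances(self) -> np.ndarray:
        """Member distances from the center, in member order."""
        w = np.asarray(self.weights)
        return np.linalg.norm((self.phenotypes - self.center) * w, axis=1)

    @property
    def center_distances(self) -> np.ndarray:
        return np.sort(self.distances())


def _as_xy(p) -> np.ndarray:
    if isinstance(p, Phenotype):
        return p.as_array()
    return np.asarray(p, dtype=float)


def generate_cloud(
    lali_type: LALIType,
    n: int,
    domain_spec: DomainSpec | None = None,
    master_seed: int = 0,
    *,
    max_spotless_frac: float = 0.10,
) -> PhenotypeCloud:
    """Simulate ``n`` patterns of one LALI-type and collect their phenotypes.

    Child seeds are derived deterministically from ``master_seed`` by a
    counter-based spawn, so the cloud is reproducible and simulations are
    independent.  Spotless or failed simulations are excluded and
    counted; more than ``max_spotless_frac`` of them aborts with an error
    (the LALI-type lies outside the patterning regime).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rows: list[np.ndarray] = []
    n_excluded = 0
    for i in range(n):
        try:
            pat = simulate_pattern(lali_type, _child_seed(master_seed, i), domain_spec)
            rows.append(measure_phenotype(pat).as_array())
        except (EmptyPatternError, sim.SimulationError):
            n_excluded += 1
            if n_excluded > max_spotless_frac * n:
                raise RuntimeError(
                    f"{n_excluded} of {i + 1} simulations produced no spots; "
                    f"LALI-type {lali_type} is outside the patterning regime"
                )
    if n_excluded:
        logger.info("cloud at %s: excluded %d/%d spotless simulations", lali_type, n_excluded, n)
    return PhenotypeCloud(
        lali_type=lali_type,
        phenotypes=np.array(rows),
        master_seed=master_seed,
        domain_spec=domain_spec,
        n_excluded=n_excluded,
    )


def cloud_center(cloud: PhenotypeCloud) -> Phenotype:
    """Componentwise mean of the cloud members."""
    c = cloud.center
    return Phenotype(FA=float(c[0]), EE=float(c[1]))


def r_cloud(cloud: PhenotypeCloud, r: float) -> tuple[np.ndarray, float]:
    """The r% of cloud members closest to the center.

    Returns (member indices, radius) with k = floor(r*n/100) members;
    the radius is the distance of the k-th closest member, ties broken
    by simulation index.  Membership of an external phenotype in the r%
    cloud is distance-to-center <= radius.
    """
    if not (0 < r <= 100):
        raise ValueError("r must lie in (0, 100]")
    k = math.floor(r * cloud.n / 100.0)
    if k == 0:
        raise ValueError(f"r = {r}% of n = {cloud.n} members selects no points")
    order = np.argsort(cloud.distances(), kind="stable")
    members = order[:k]
    radius = float(cloud.distances()[members[-1]])
    return members, radius


def contains(cloud: PhenotypeCloud, r: float, phenotype) -> bool:
    """True iff the phenotype lies within the r% cloud radius of the center."""
    _, radius = r_cloud(cloud, r)
    w = np.asarray(cloud.weights)
    dist = float(np.linalg.norm((_as_xy(phenotype) - cloud.center) * w))
    return dist <= radius


# --------------------------------------------------------------------------
# neutral regions
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamGrid:
    """A rectangular grid over the 2-D varied coordinates of one model."""

    model: str
    axes: tuple[str, str]
    values: tuple[tuple[float, ...], tuple[float, ...]]
    fixed: tuple[tuple[str, float], ...] = ()

    def __init__(self, model, axes, values, fixed=None):
        object.__setattr__(self, "model", model)
        object.__setattr__(self, "axes", tuple(axes))
        object.__setattr__(
            self, "values", tuple(tuple(float(x) for x in vs) for vs in values)
        )
        object.__setattr__(self, "fixed", tuple(sorted(dict(fixed or {}).items())))
        if len(self.axes) != 2 or len(self.values) != 2:
            raise ValueError("ParamGrid is 2-D: two axes, two value vectors")
        if not all(self.values):
            raise ValueError("grid axes must be nonempty")

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.values[0]), len(self.values[1]))

    def point(self, i: int, j: int) -> LALIType:
        coords = {self.axes[0]: self.values[0][i], self.axes[1]: self.values[1][j]}
        return LALIType(self.model, coords=coords, fixed=dict(self.fixed))

    def points(self):
        for i in range(self.shape[0]):
            for j in range(self.shape[1]):
                yield (i, j), self.point(i, j)


class CloudCache(dict):
    """Cache of generated clouds keyed by (LALI-type, n, domain, seed).

    Neutral-region scans for several phenotypes over the same grid, the
    grid -> phenotype map, and relatedness scoring all reuse clouds, so
    one scan's simulations serve every subsequent query.
    """

    def get_or_generate(
        self,
        lali_type: LALIType,
        n: int,
        domain_spec: DomainSpec | None,
        master_seed: int,
    ) -> PhenotypeCloud:
        key = (lali_type, n, domain_spec, master_seed)
        if key not in self:
            self[key] = generate_cloud(lali_type, n, domain_spec, master_seed)
        return self[key]


@dataclass
class NeutralRegion:
    """Membership of a phenotype's r% neutral region over a grid.

    A grid point belongs to the region when the phenotype lies within
    the r% phenotype cloud of that LALI-type.  ``failed`` flags points
    whose clouds could not be generated; they are never members.
    """

    phenotype: np.ndarray
    grid: ParamGrid
    r: float
    n_per_point: int
    membership: np.ndarray
    failed: np.ndarray
    master_seed: int

    def representative(self, cache: CloudCache, domain_spec=None) -> LALIType | None:
        """The member LALI-type whose cloud center is nearest the phenotype."""
        best, best_d = None, np.inf
        for (i, j), lt in self.grid.points():
            if not self.membership[i, j]:
                continue
            cloud = cache.get_or_generate(lt, self.n_per_point, domain_spec, self.master_seed)
            d = float(np.linalg.norm(cloud.center - self.phenotype))
            if d < best_d:
                best, best_d = lt, d
        return best


def neutral_region_scan(
    phenotype,
    grid: ParamGrid,
    r: float = 50.0,
    n_per_point: int = 50,
    master_seed: int = 0,
    *,
    domain_spec: DomainSpec | None = None,
    cache: CloudCache | None = None,
) -> NeutralRegion:
    """Scan a LALI-space grid for the r% neutral region of a phenotype.

    Each grid point's cloud is generated once (or taken from ``cache``)
    under a seeding scheme shared across phenotypes, so scanning several
    phenotypes over one grid costs one set of simulations.  Per-point
    simulation failures are flagged, not fatal.
    """
    if n_per_point < 10:
        raise ValueError("n_per_point must be >= 10")
    cache = cache if cache is not None else CloudCache()
    target = _as_xy(phenotype)
    membership = np.zeros(grid.shape, dtype=bool)
    failed = np.zeros(grid.shape, dtype=bool)
    for (i, j), lt in grid.points():
        try:
            cloud = cache.get_or_generate(lt, n_per_point, domain_spec, master_seed)
        except (RuntimeError, ValueError) as exc:
            logger.warning("grid point %s failed: %s", lt, exc)
            failed[i, j] = True
            continue
        membership[i, j] = contains(cloud, r, target)
    return NeutralRegion(
        phenotype=target,
        grid=grid,
        r=r,
        n_per_point=n_per_point,
        membership=membership,
        failed=failed,
        master_seed=master_seed,
    )


# --------------------------------------------------------------------------
# best match, relatedness, grid map
# --------------------------------------------------------------------------

def best_match(
    phenotype,
    lali_type: LALIType,
    n: int = 100,
    domain_spec: DomainSpec | None = None,
    master_seed: int = 0,
) -> tuple[BinaryPattern, Phenotype, float]:
    """The simulated pattern closest to a target phenotype.

    Simulates ``n`` patterns of the LALI-type and returns the one whose
    [FA, EE] minimizes the Euclidean distance to the target (ties broken
    by seed index), with its phenotype and distance.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    target = _as_xy(phenotype)
    best = None
    n_failed = 0
    for i in range(n):
        try:
            pat = simulate_pattern(lali_type, _child_seed(master_seed, i), domain_spec)
            ph = measure_phenotype(pat)
        except (EmptyPatternError, sim.SimulationError):
            n_failed += 1
            continue
        d = float(np.linalg.norm(ph.as_array() - target))
        if best is None or d < best[2]:
            best = (pat, ph, d)
    if best is None:
        raise RuntimeError(f"all {n} simulations at {lali_type} produced no spots")
    return best


def relatedness(
    phenotype_i,
    phenotype_j,
    clouds_i: dict[str, PhenotypeCloud],
    clouds_j: dict[str, PhenotypeCloud],
    r: float = 95.0,
) -> int:
    """0-4 relatedness score between two phenotypes.

    For each of the two models, tests whether phenotype i lies in the r%
    cloud of j's representative LALI-type and vice versa; the score is
    the number of true outcomes among the four combinations (two
    directions x two models).  0 means neither pattern is a plausible
    noise-variant of the other under either model; 4 means mutual
    containment under both.
    """
    models = sorted(set(clouds_i) | set(clouds_j))
    score = 0
    for m in models:
        if m not in clouds_i or m not in clouds_j:
            raise ValueError(f"missing cloud for model {m!r}")
        score += contains(clouds_j[m], r, phenotype_i)
        score += contains(clouds_i[m], r, phenotype_j)
    return int(score)


def relatedness_matrix(
    phenotypes: list,
    clouds: list[dict[str, PhenotypeCloud]],
    r: float = 95.0,
) -> np.ndarray:
    """Symmetric matrix of pairwise relatedness scores.

    ``clouds[i]`` maps model name -> cloud for phenotype i (LALI-types
    drawn from each phenotype's neutral region).  The diagonal scores
    each phenotype against its own clouds.
    """
    m = len(phenotypes)
    if len(clouds) != m:
        raise ValueError("need one cloud dict per phenotype")
    out = np.zeros((m, m), dtype=int)
    for i in range(m):
        for j in range(i, m):
            out[i, j] = out[j, i] = relatedness(
                phenotypes[i], phenotypes[j], clouds[i], clouds[j], r
            )
    return out


@dataclass
class GridPhenotypeMap:
    """Cloud centers of every point of a LALI-space grid.

    ``centers`` has shape (n_i, n_j, 2) of [FA, EE]; NaN where a point
    failed.  The map renders LALI-space isoclines in phenotype space and
    quantifies the mapping bias: :meth:`bias_fraction` reports what
    fraction of LALI-space area lands inside a phenotype-space rectangle
    (each grid cell carries equal area).
    """

    grid: ParamGrid
    centers: np.ndarray
    failed: np.ndarray
    n_per_point: int
    master_seed: int

    def bias_fraction(self, fa_range: tuple[float, float], ee_range: tuple[float, float]) -> float:
        ok = ~self.failed
        if not ok.any():
            raise ValueError("all grid points failed")
        fa = self.centers[..., 0]
        ee = self.centers[..., 1]
        inside = (
            ok
            & (fa >= fa_range[0]) & (fa < fa_range[1])
            & (ee >= ee_range[0]) & (ee < ee_range[1])
        )
        return float(inside.sum()) / float(ok.sum())


def grid_phenotype_map(
    grid: ParamGrid,
    n_per_point: int = 100,
    master_seed: int = 0,
    *,
    domain_spec: DomainSpec | None = None,
    cache: CloudCache | None = None,
) -> GridPhenotypeMap:
    """Map a regular LALI-space grid to its cloud centers in phenotype space."""
    cache = cache if cache is not None else CloudCache()
    centers = np.full(grid.shape + (2,), np.nan)
    failed = np.zeros(grid.shape, dtype=bool)
    for (i, j), lt in grid.points():
        try:
            cloud = cache.get_or_generate(lt, n_per_point, domain_spec, master_seed)
        except (RuntimeError, ValueError) as exc:
            logger.warning("grid point %s failed: %s", lt, exc)
            failed[i, j] = True
            continue
        centers[i, j] = cloud.center
    return GridPhenotypeMap(
        grid=grid,
        centers=centers,
        failed=failed,
        n_per_point=n_per_point,
        master_seed=master_seed,
    )
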