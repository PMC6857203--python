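"""Two-population demographic models and coalescent simulation.

Eight demographic models describe a pair of diverging populations (labelled
K and W): four gene-flow scenarios crossed with two effective-size regimes.

Gene-flow scenarios (backward time, present = 0, split at ``T``):

* ``ISO`` -- isolation: no migration at any time;
* ``IM``  -- isolation with migration: gene flow over the whole divergence
  ``[0, T)``;
* ``EM``  -- early migration: gene flow only in the ancient part of the
  divergence ``[T1, T)``;
* ``SC``  -- secondary contact: gene flow only recently, ``[0, T1)``.

Size regimes:

* group ``A`` -- each descendant population keeps a constant diploid size
  (``Ne_K``, ``Ne_W``) from the split to the present;
* group ``B`` -- sizes are ``Ne_K``/``Ne_W`` in the old epoch ``[T1, T)`` and
  change exponentially from ``N0_K``/``N0_W`` (present) back to
  ``Ne_K``/``Ne_W`` at ``T1``.

At ``T`` the two populations merge into a single ancestral population of
diploid size ``Ne_A``.  Migration strength is given as ``2NM`` -- the number
of immigrant individuals entering the recipient population per generation --
so the backward per-lineage migration rate in recipient *i* is
``M / (2 N_i(t))`` per generation.

User-facing parameters are in natural units (years, diploid individuals);
conversion to coalescent units (time in ``4 N_ref`` generations, relative
sizes, ``theta = 4 N_ref mu L``) happens in :func:`build_timeline` with a
fixed reference size ``N_ref``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from . import _engine

SCENARIOS = ("ISO", "IM", "EM", "SC")
GROUPS = ("A", "B")
MODEL_NAMES = tuple(f"{s}-{g}" for g in GROUPS for s in SCENARIOS)


@dataclass(frozen=True)
class ModelId:
    """One of the eight demographic models, e.g. ``ModelId('SC', 'B')``."""

    scenario: str
    group: str

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown gene-flow scenario {self.scenario!r}")
        if self.group not in GROUPS:
            raise ValueError(f"unknown size-regime group {self.group!r}")

    @classmethod
    def parse(cls, name: str | "ModelId") -> "ModelId":
        if isinstance(name, ModelId):
            return name
        scenario, _, group = name.partition("-")
        return cls(scenario, group)

    @property
    def name(self) -> str:
        return f"{self.scenario}-{self.group}"

    @property
    def has_migration(self) -> bool:
        return self.scenario != "ISO"

    @property
    def changing_ne(self) -> bool:
        return self.group == "B"

    @property
    def uses_t1(self) -> bool:
        """Whether T1 is a live parameter (size shift or gene-flow change)."""
        return self.group == "B" or self.scenario in ("EM", "SC")

    def __str__(self) -> str:  # pragma: no cover
        return self.name


@dataclass
class ParameterSet:
    """Demographic parameters in natural units (years, diploid individuals).

    ``T``/``T1`` in years; sizes in diploid individuals; migration as 2NM
    immigrant individuals per generation into the named recipient.
    """

    T: float
    Ne_K: float
    Ne_W: float
    Ne_A: float
    M_WtoK: float = 0.0
    M_KtoW: float = 0.0
    T1: float | None = None
    N0_K: float | None = None
    N0_W: float | None = None

    def validate(self, model: ModelId) -> None:
        if not (self.T > 0 and self.Ne_K > 0 and self.Ne_W > 0 and self.Ne_A > 0):
            raise ValueError("times and sizes must be strictly positive")
        if self.M_WtoK < 0 or self.M_KtoW < 0:
            raise ValueError("migration must be non-negative")
        if model.scenario == "ISO" and (self.M_WtoK != 0 or self.M_KtoW != 0):
            raise ValueError("isolation model requires zero migration")
        if model.uses_t1:
            if self.T1 is None or not (0 < self.T1 < self.T):
                raise ValueError("T1 must satisfy 0 < T1 < T")
        if model.changing_ne:
            if self.N0_K is None or self.N0_W is None:
                raise ValueError("group B models need present-day sizes N0_K, N0_W")
            if self.N0_K <= 0 or self.N0_W <= 0:
                raise ValueError("present-day sizes must be strictly positive")

    def growth_coefficients(self, gen_time: float) -> tuple[float, float]:
        """Per-generation exponential growth coefficients implied by the
        endpoint sizes (derived, group B only)."""
        if self.T1 is None or self.N0_K is None or self.N0_W is None:
            raise ValueError("growth is defined only for changing-size models")
        gens = self.T1 / gen_time
        return (math.log(self.Ne_K / self.N0_K) / gens,
                math.log(self.Ne_W / self.N0_W) / gens)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def model_param_names(model: ModelId | str) -> list[str]:
    """Ordered free-parameter names for a model (the ABC target vector)."""
    model = ModelId.parse(model)
    names = ["T", "Ne_K", "Ne_W", "Ne_A"]
    if model.uses_t1:
        names.append("T1")
    if model.has_migration:
        names += ["M_WtoK", "M_KtoW"]
    if model.changing_ne:
        names += ["N0_K", "N0_W"]
    return names


# ---------------------------------------------------------------------------
# priors

@dataclass
class PriorSet:
    """Per-parameter prior specifications.

    Each entry maps a parameter name to a tuple:
    ``("loguniform", lo, hi)``, ``("uniform", lo, hi)`` or
    ``("truncnorm", mean, sd)`` (the latter truncated to ``(t1_min, T)`` and
    used for T1).
    """

    specs: dict = field(default_factory=dict)
    t1_min: float = 1e3  # years; lower truncation bound for T1

    def __post_init__(self):
        for name, spec in self.specs.items():
            kind, a, b = spec
            if kind in ("loguniform", "uniform") and not (a < b):
                raise ValueError(f"empty support for prior on {name}")
            if kind == "loguniform" and a <= 0:
                raise ValueError(f"log-uniform prior on {name} needs positive support")
            if kind == "truncnorm" and b <= 0:
                raise ValueError(f"truncated-normal prior on {name} needs sd > 0")


def default_priors() -> PriorSet:
    """Default priors: log-uniform sizes, uniform split time and migration,
    truncated-normal T1 (units: years, individuals)."""
    return PriorSet({
        "Ne_K": ("loguniform", 1e4, 1e7),
        "Ne_W": ("loguniform", 1e4, 1e7),
        "Ne_A": ("loguniform", 1e4, 1e7),
        "N0_K": ("loguniform", 1e4, 1e7),
        "N0_W": ("loguniform", 1e4, 1e7),
        "T": ("uniform", 0.2e6, 2.0e6),
        "T1": ("truncnorm", 0.06e6, 0.02e6),
        "M_WtoK": ("uniform", 0.0, 500.0),
        "M_KtoW": ("uniform", 0.0, 500.0),
    })


def _draw(spec, n, rng):
    kind, a, b = spec
    if kind == "loguniform":
        return np.exp(rng.uniform(np.log(a), np.log(b), size=n))
    if kind == "uniform":
        return rng.uniform(a, b, size=n)
    raise ValueError(f"unknown prior kind {kind!r}")


def sample_prior_batch(priors: PriorSet, model: ModelId | str, n: int,
                       rng: np.random.Generator) -> dict:
    """Vectorised prior draws; returns dict of name -> array of length n."""
    model = ModelId.parse(model)
    names = model_param_names(model)
    out = {}
    for name in names:
        if name == "T1":
            continue
        out[name] = _draw(priors.specs[name], n, rng)
    if "T1" in names:
        kind, mean, sd = priors.specs["T1"]
        if kind != "truncnorm":
            out["T1"] = np.clip(_draw(priors.specs["T1"], n, rng),
                                priors.t1_min, out["T"])
        else:
            t1 = np.empty(n)
            T = out["T"]
            todo = np.arange(n)
            for _ in range(1000):
                draws = rng.normal(mean, sd, size=todo.size)
                ok = (draws > priors.t1_min) & (draws < T[todo])
                t1[todo[ok]] = draws[ok]
                todo = todo[~ok]
                if todo.size == 0:
                    break
            else:
                raise RuntimeError(
                    "T1 prior has no mass in (t1_min, T) after 1000 rejection rounds")
            out["T1"] = t1
    return out


def sample_prior(priors: PriorSet, model: ModelId | str,
                 seed: int | np.random.Generator) -> ParameterSet:
    """Draw a single ParameterSet from the priors for ``model``."""
    model = ModelId.parse(model)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    draws = sample_prior_batch(priors, model, 1, rng)
    params = ParameterSet(T=float(draws["T"][0]),
                          Ne_K=float(draws["Ne_K"][0]),
                          Ne_W=float(draws["Ne_W"][0]),
                          Ne_A=float(draws["Ne_A"][0]))
    for name in ("T1", "M_WtoK", "M_KtoW", "N0_K", "N0_W"):
        if name in draws:
            setattr(params, name, float(draws[name][0]))
    params.validate(model)
    return params


# ---------------------------------------------------------------------------
# timelines

@dataclass
class LocusConfig:
    """Locus geometry and molecular clock.

    mu is per site per generation; gen_time in years; n_ref is the fixed
    reference diploid size used for coalescent scaling.
    """

    length: int = 10_000
    mu: float = 0.8e-8
    gen_time: float = 2.5
    n_ref: float = 1e6

    @property
    def theta(self) -> float:
        """theta = 4 N_ref mu L, the locus mutation rate in coalescent units."""
        return 4.0 * self.n_ref * self.mu * self.length

    def years_to_units(self, years: float) -> float:
        return years / self.gen_time / (4.0 * self.n_ref)


@dataclass
class Timeline:
    """Scaled piecewise demography consumed by the event engine."""

    array: np.ndarray
    model: ModelId
    config: LocusConfig

    @property
    def boundaries(self) -> list[float]:
        """Epoch start times (coalescent units), including the present."""
        t1, tT = self.array[_engine.TL_T1], self.array[_engine.TL_TT]
        return [0.0, t1, tT] if t1 > 0 else [0.0, tT]

    @property
    def boundaries_generations(self) -> list[float]:
        scale = 4.0 * self.config.n_ref
        return [b * scale for b in self.boundaries]

    @property
    def migration_matrices(self) -> list[np.ndarray]:
        """Per-epoch 2x2 backward migration-rate numerators (row = recipient)."""
        a = self.array
        out = []
        eps = [(a[_engine.TL_MK0], a[_engine.TL_MW0]),
               (a[_engine.TL_MK1], a[_engine.TL_MW1])]
        if a[_engine.TL_T1] <= 0:
            eps = eps[1:]
        for mK, mW in eps:
            out.append(np.array([[0.0, mK], [mW, 0.0]]))
        out.append(np.zeros((2, 2)))
        return out


def build_timeline(params: ParameterSet, model: ModelId | str,
                   config: LocusConfig | None = None) -> Timeline:
    """Convert natural-unit parameters into a scaled event-engine timeline."""
    model = ModelId.parse(model)
    config = config or LocusConfig()
    params.validate(model)
    batch = build_timelines_batch(
        {k: np.asarray([v]) for k, v in params.as_dict().items()
         if v is not None}, model, config)
    if not np.all(np.isfinite(batch)):
        raise ValueError("non-finite timeline after unit conversion")
    return Timeline(batch[0], model, config)


def build_timelines_batch(draws: dict, model: ModelId | str,
                          config: LocusConfig) -> np.ndarray:
    """Vectorised timeline construction; ``draws`` maps names to arrays."""
    model = ModelId.parse(model)
    n = len(draws["T"])
    nref = config.n_ref
    tl = np.zeros((n, _engine.TL_LEN))
    tT = config.years_to_units(np.asarray(draws["T"], dtype=float))
    tl[:, _engine.TL_TT] = tT
    tl[:, _engine.TL_NA] = np.asarray(draws["Ne_A"], dtype=float) / nref
    neK = np.asarray(draws["Ne_K"], dtype=float) / nref
    neW = np.asarray(draws["Ne_W"], dtype=float) / nref
    tl[:, _engine.TL_NK1] = neK
    tl[:, _engine.TL_NW1] = neW

    if model.uses_t1:
        t1 = config.years_to_units(np.asarray(draws["T1"], dtype=float))
    else:
        t1 = np.zeros(n)  # no T1 boundary: epoch 0 is empty
    tl[:, _engine.TL_T1] = t1

    if model.changing_ne:
        n0K = np.asarray(draws["N0_K"], dtype=float) / nref
        n0W = np.asarray(draws["N0_W"], dtype=float) / nref
        tl[:, _engine.TL_NK0] = n0K
        tl[:, _engine.TL_NW0] = n0W
        with np.errstate(divide="ignore"):
            tl[:, _engine.TL_AK] = np.log(neK / n0K) / t1
            tl[:, _engine.TL_AW] = np.log(neW / n0W) / t1
    else:
        tl[:, _engine.TL_NK0] = neK
        tl[:, _engine.TL_NW0] = neW

    if model.has_migration:
        mK = 2.0 * np.asarray(draws["M_WtoK"], dtype=float)  # into K
        mW = 2.0 * np.asarray(draws["M_KtoW"], dtype=float)  # into W
        if model.scenario in ("IM", "SC"):
            tl[:, _engine.TL_MK0] = mK
            tl[:, _engine.TL_MW0] = mW
        if model.scenario in ("IM", "EM"):
            tl[:, _engine.TL_MK1] = mK
            tl[:, _engine.TL_MW1] = mW
    if not np.all(np.isfinite(tl)):
        raise ValueError("non-finite timeline after unit conversion")
    return tl


# ---------------------------------------------------------------------------
# genealogies and haplotypes

@dataclass
class Tree:
    """Coalescent genealogy over ``n_K + n_W`` tips.

    Node times are in coalescent units of ``4 N_ref`` generations; ``parent``
    is -1 at the root; ``masks[i]`` is the 64-bit set of tips below node i.
    """

    parent: np.ndarray
    time: np.ndarray
    masks: np.ndarray
    n_K: int
    n_W: int

    @property
    def n_tips(self) -> int:
        return self.n_K + self.n_W

    @property
    def tmrca(self) -> float:
        return float(self.time.max())

    @property
    def branch_lengths(self) -> np.ndarray:
        """Branch length above each non-root node (root entry = 0)."""
        out = np.zeros_like(self.time)
        has_parent = self.parent >= 0
        out[has_parent] = self.time[self.parent[has_parent]] - self.time[has_parent]
        return out

    @property
    def total_branch_length(self) -> float:
        return float(self.branch_lengths.sum())

    @property
    def tip_populations(self) -> np.ndarray:
        return np.array(["K"] * self.n_K + ["W"] * self.n_W)


@dataclass
class HaplotypeData:
    """Phased binary haplotypes for one locus.

    ``matrix`` is haplotypes x segregating sites with 0/1 entries (derived
    allele indicators); positions are strictly increasing bp offsets in
    ``[0, L)``.
    """

    matrix: np.ndarray
    positions: np.ndarray
    pops: np.ndarray
    length: int

    def __post_init__(self):
        if self.matrix.shape[1] != len(self.positions):
            raise ValueError("positions do not match matrix columns")
        if self.matrix.shape[0] != len(self.pops):
            raise ValueError("population labels do not match haplotype rows")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def dosages(self) -> np.ndarray:
        """Diploid dosage matrix by sequential pairing of haplotypes."""
        n = self.matrix.shape[0]
        if n % 2:
            raise ValueError("odd number of haplotypes cannot be diploidized")
        return self.matrix[0::2].astype(np.int8) + self.matrix[1::2].astype(np.int8)

    def diploid_pops(self) -> np.ndarray:
        return self.pops[0::2]


def simulate_genealogy(timeline: Timeline, n_K: int, n_W: int,
                       seed: int) -> Tree:
    """Draw one genealogy under the structured coalescent."""
    if n_K + n_W < 2:
        raise ValueError("need at least two sampled haplotypes")
    if n_K + n_W > 64:
        raise ValueError("sample sizes above 64 haplotypes are not supported")
    parent, node_time, masks, status = _engine.simulate_tree(
        timeline.array, n_K, n_W, np.uint32(seed % (2 ** 32)))
    if status != 0:
        raise RuntimeError("event cap exceeded in coalescent simulation")
    return Tree(parent=parent, time=node_time, masks=masks, n_K=n_K, n_W=n_W)


def drop_mutations(tree: Tree, theta: float, length: int,
                   rng: np.random.Generator) -> HaplotypeData:
    """Place infinite-sites mutations on a genealogy.

    Per-branch mutation counts are Poisson(branch length * theta) with branch
    lengths in 4*N_ref generations; each mutation gets a distinct position
    (sampling without replacement over the L bp grid approximates the
    infinite-sites model at finite locus length).
    """
    if theta < 0:
        raise ValueError("theta must be non-negative")
    bl = tree.branch_lengths
    counts = rng.poisson(bl * theta)
    S = int(counts.sum())
    if S > length:
        raise ValueError("more mutations than available positions; increase L")
    positions = np.sort(rng.choice(length, size=S, replace=False))
    n = tree.n_tips
    site_masks = np.repeat(tree.masks, counts)
    # shuffle which mutation gets which position (order within branch irrelevant)
    rng.shuffle(site_masks)
    bits = (site_masks[None, :] >> np.arange(n, dtype=np.uint64)[:, None]
            ).astype(np.uint8) & 1
    return HaplotypeData(matrix=bits, positions=positions,
                         pops=tree.tip_populations, length=length)


def simulate_dataset(model: ModelId | str, params: ParameterSet, n_loci: int,
                     locus_config: LocusConfig | None = None, *,
                     n_K: int = 20, n_W: int = 20,
                     seed: int = 0) -> list[HaplotypeData]:
    """Simulate independent loci (free recombination between, none within).

    Per-locus random streams are derived from ``seed`` by counter, so
    increasing ``n_loci`` leaves earlier loci unchanged.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    model = ModelId.parse(model)
    cfg = locus_config or LocusConfig()
    timeline = build_timeline(params, model, cfg)
    loci = []
    for j in range(n_loci):
        ss = np.random.SeedSequence(entropy=seed, spawn_key=(j,))
        tree_seed = int(ss.generate_state(1, np.uint32)[0])
        tree = simulate_genealogy(timeline, n_K, n_W, tree_seed)
        rng = np.random.default_rng(ss.spawn(1)[0])
        loci.append(drop_mutations(tree, cfg.theta, cfg.length, rng))
    return loci


def simulate_locus_stats(timelines: np.ndarray, n_K: int, n_W: int,
                         config: LocusConfig, n_loci: int,
                         seed: int | np.random.SeedSequence,
                         r2_exact_cap: int = 300,
                         r2_sample_pairs: int = 200) -> np.ndarray:
    """Fast path: per-locus statistics for a batch of timelines.

    Returns an array of shape (n_sims, n_loci, N_STATS) in the
    :mod:`divergesim._engine` statistic order.  Statistics are computed from
    branch-level mutation counts without materialising haplotype matrices;
    the mean-r^2 statistic is exact when the number of site pairs is at most
    ``r2_exact_cap`` and otherwise estimated from ``r2_sample_pairs``
    uniformly sampled site pairs (unbiased).
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    n_sims = timelines.shape[0]
    seeds = ss.generate_state(n_sims * n_loci, np.uint32).reshape(n_sims, n_loci)
    return _engine.simulate_stats_batch(
        np.ascontiguousarray(timelines, dtype=np.float64), n_K, n_W,
        config.theta, float(config.length), n_loci, seeds,
        r2_exact_cap, r2_sample_pairs)
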