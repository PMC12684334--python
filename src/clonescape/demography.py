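"""Two-population demographic inference on the folded joint SFS.

The joint site frequency spectrum (jSFS) of two populations — the 2-D
histogram of derived/minor allele counts — carries the signature of
their divergence history.  This module ranks the 22 canonical two-deme
scenarios built from four base histories:

* SI — strict isolation since the split,
* IM — isolation with continuous migration,
* AM — ancestral migration that later stopped,
* SC — secondary contact after a period of isolation,

each optionally extended with exponential growth (G, possibly
asymmetric), two effective-size classes of loci standing in for linked
selection (2N: a proportion Q of the genome at a reduced size), and two
migration-rate classes standing in for barrier loci (2m: a proportion P
of the genome at reduced migration; only with gene flow).

Expected spectra come from structured-coalescent Monte Carlo (module
:mod:`clonescape._coalescent`) rather than a diffusion solver; fitting
maximises a composite Poisson likelihood over jSFS cells with the
spectrum scale theta profiled out analytically, using a three-step
search (broad random search, Nelder–Mead refinement, perturbation
restarts) repeated ``n_fits`` times.  Models are compared by AIC with a
conservative dAIC < -10 rule.  Scaled parameters convert to biological
units via the mutation rate, an effective sequence length and the
generation time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution, minimize
from scipy.special import gammaln

from . import _coalescent
from .genio import MISSING, SNPMatrix

__all__ = [
    "JointSFS",
    "DemographicModel",
    "FitResult",
    "JointSFSModel",
    "model_registry",
    "get_model",
    "build_jsfs",
    "fold_jsfs",
    "expected_jsfs",
    "fit_model",
    "compare_models",
    "to_biological",
    "to_scaled",
]


# ------------------------------------------------------------------ jSFS

@dataclass
class JointSFS:
    """(2n1+1) x (2n2+1) allele-count histogram for two populations."""

    counts: np.ndarray
    folded: bool
    pop_labels: tuple[str, str] = ("pop1", "pop2")

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("jSFS must be 2-D")
        if (self.counts < 0).any():
            raise ValueError("jSFS counts must be >= 0")

    @property
    def n1(self) -> int:
        """Haploid sample size of population 1."""
        return self.counts.shape[0] - 1

    @property
    def n2(self) -> int:
        return self.counts.shape[1] - 1

    def total(self) -> float:
        return float(self.counts.sum())

    def fold(self) -> "JointSFS":
        return fold_jsfs(self)

    def mask(self) -> np.ndarray:
        """Cells entering the likelihood: support minus the fixed corners."""
        if self.folded:
            supp = _fold_array(np.ones_like(self.counts)) > 0
        else:
            supp = np.ones_like(self.counts, dtype=bool)
        supp[0, 0] = False
        supp[self.n1, self.n2] = False
        return supp

    # plain-text round trip -----------------------------------------
    def to_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# n1={self.n1} n2={self.n2} folded={int(self.folded)} "
                f"pops={self.pop_labels[0]},{self.pop_labels[1]}\n"
            )
            np.savetxt(fh, self.counts, fmt="%.8g", delimiter="\t")

    @classmethod
    def from_text(cls, path) -> "JointSFS":
        with open(path) as fh:
            header = fh.readline()
            fields = dict(
                kv.split("=", 1) for kv in header.lstrip("# ").split() if "=" in kv
            )
            counts = np.loadtxt(fh, delimiter="\t", ndmin=2)
        pops = tuple(fields.get("pops", "pop1,pop2").split(","))
        return cls(counts, folded=bool(int(fields["folded"])), pop_labels=pops)


def build_jsfs(m: SNPMatrix, pop1: set[str], pop2: set[str]) -> JointSFS:
    """Tally the unfolded jSFS of two site-sets from a genotype matrix.

    Loci with any missing call among the selected individuals are
    dropped.  Entry (i, j) counts loci with ALT-allele count i in pop1
    and j in pop2.
    """
    pop1, pop2 = set(pop1), set(pop2)
    if pop1 & pop2:
        raise ValueError(f"populations overlap: {sorted(pop1 & pop2)}")
    idx1 = [i for i, s in enumerate(m.site_of_individual) if s in pop1]
    idx2 = [i for i, s in enumerate(m.site_of_individual) if s in pop2]
    if not idx1 or not idx2:
        raise ValueError("both populations must contain individuals")
    d1 = m.dosages[idx1]
    d2 = m.dosages[idx2]
    ok = ~((d1 == MISSING).any(axis=0) | (d2 == MISSING).any(axis=0))
    i_counts = d1[:, ok].sum(axis=0)
    j_counts = d2[:, ok].sum(axis=0)
    n1h, n2h = 2 * len(idx1), 2 * len(idx2)
    counts = np.zeros((n1h + 1, n2h + 1))
    np.add.at(counts, (i_counts, j_counts), 1.0)
    return JointSFS(counts, folded=False, pop_labels=("pop1", "pop2"))


def _fold_array(arr: np.ndarray) -> np.ndarray:
    """Fold on the pooled minor-allele count.

    Cells with pooled derived count above half merge into their
    complement; complementary pairs sitting exactly at half are averaged
    (the average stored in both cells, preserving the total and making
    folding idempotent).
    """
    n1 = arr.shape[0] - 1
    n2 = arr.shape[1] - 1
    half = (n1 + n2) / 2.0
    out = np.zeros_like(np.asarray(arr, dtype=float))
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            if i + j < half:
                out[i, j] += arr[i, j]
            elif i + j > half:
                out[n1 - i, n2 - j] += arr[i, j]
            else:  # exactly half: averaged with the complement once
                out[i, j] += 0.5 * arr[i, j] + 0.5 * arr[n1 - i, n2 - j]
    return out


def fold_jsfs(s: JointSFS) -> JointSFS:
    """Fold a jSFS on pooled minor-allele count; idempotent."""
    if s.folded:
        return JointSFS(s.counts.copy(), folded=True, pop_labels=s.pop_labels)
    return JointSFS(_fold_array(s.counts), folded=True, pop_labels=s.pop_labels)


# -------------------------------------------------------- model space

_SIZE_BOUNDS = (0.05, 20.0)
_TIME_BOUNDS = (0.05, 10.0)
_MIG_BOUNDS = (0.1, 20.0)
_FRAC_BOUNDS = (0.05, 0.95)
_RATIO_BOUNDS = (0.05, 10.0)
_HRF_BOUNDS = (0.05, 1.0)
_MEFRAC_BOUNDS = (1e-3, 0.2)


@dataclass(frozen=True)
class DemographicModel:
    """One of the 22 two-deme divergence scenarios.

    Scaled parameters (time unit 2*N_ref generations, sizes relative to
    N_ref, migration per lineage per time unit):

    nu1, nu2   present deme sizes          na        ancestral size
    ts         split time                  m12, m21  migration rates
    tam_frac   AM: migration stops at tam_frac * ts before present
    tsc_frac   SC: contact began at tsc_frac * ts before present
    r1, r2     G: size at the split / present size (per deme)
    hrf, Q     2N: reduced-size factor and affected genome proportion
    me_frac, P 2m: migration-reduction factor and affected proportion
    """

    name: str
    base: str
    growth: bool = False
    two_n: bool = False
    two_m: bool = False

    def __post_init__(self):
        if self.base not in ("SI", "IM", "AM", "SC"):
            raise ValueError(f"unknown base history {self.base!r}")
        if self.two_m and self.base == "SI":
            raise ValueError("2m requires a history with migration")
        if self.two_m and self.two_n:
            raise ValueError("2N and 2m are not combined in the scenario set")

    @property
    def has_migration(self) -> bool:
        return self.base in ("IM", "AM", "SC")

    @property
    def param_names(self) -> list[str]:
        names = ["nu1", "nu2", "na", "ts"]
        if self.has_migration:
            names += ["m12", "m21"]
        if self.base == "AM":
            names += ["tam_frac"]
        if self.base == "SC":
            names += ["tsc_frac"]
        if self.growth:
            names += ["r1", "r2"]
        if self.two_n:
            names += ["hrf", "Q"]
        if self.two_m:
            names += ["me_frac", "P"]
        return names

    @property
    def bounds(self) -> dict[str, tuple[float, float]]:
        b = {
            "nu1": _SIZE_BOUNDS,
            "nu2": _SIZE_BOUNDS,
            "na": _SIZE_BOUNDS,
            "ts": _TIME_BOUNDS,
            "m12": _MIG_BOUNDS,
            "m21": _MIG_BOUNDS,
            "tam_frac": _FRAC_BOUNDS,
            "tsc_frac": _FRAC_BOUNDS,
            "r1": _RATIO_BOUNDS,
            "r2": _RATIO_BOUNDS,
            "hrf": _HRF_BOUNDS,
            "Q": _FRAC_BOUNDS,
            "me_frac": _MEFRAC_BOUNDS,
            "P": _FRAC_BOUNDS,
        }
        return {k: b[k] for k in self.param_names}

    @property
    def k(self) -> int:
        """Free-parameter count, including the profiled spectrum scale."""
        return len(self.param_names) + 1


def model_registry() -> list[DemographicModel]:
    """All 22 scenarios: SI{,G,2N,2NG} and IM/AM/SC{,G,2N,2m,2NG,2mG}."""
    models = []
    for base in ("SI", "IM", "AM", "SC"):
        variants = [("", {}), ("G", {"growth": True}), ("2N", {"two_n": True})]
        if base != "SI":
            variants.append(("2m", {"two_m": True}))
        variants.append(("2NG", {"two_n": True, "growth": True}))
        if base != "SI":
            variants.append(("2mG", {"two_m": True, "growth": True}))
        for suffix, flags in variants:
            models.append(DemographicModel(name=base + suffix, base=base, **flags))
    return models


def get_model(name: str) -> DemographicModel:
    for m in model_registry():
        if m.name == name:
            return m
    raise KeyError(f"unknown demographic model {name!r}")


# ------------------------------------------- epochs & expected spectra

_N_GROWTH_STEPS = 8


def _locus_classes(model: DemographicModel, p: dict) -> list[tuple[float, dict]]:
    """Mixture of locus classes: (weight, parameter overrides)."""
    if model.two_n:
        q = p["Q"]
        return [(1.0 - q, {}), (q, {"size_factor": p["hrf"]})]
    if model.two_m:
        pp = p["P"]
        return [(1.0 - pp, {}), (pp, {"mig_factor": p["me_frac"]})]
    return [(1.0, {})]


def _epoch_arrays(model: DemographicModel, p: dict, size_factor=1.0, mig_factor=1.0):
    """Piecewise-constant history on [0, ts) + ancestral size.

    Exponential growth is discretised into midpoint-evaluated
    sub-epochs; migration epochs follow the base history.
    """
    ts = p["ts"]
    breaks = {0.0, ts}
    if model.base == "AM":
        breaks.add(p["tam_frac"] * ts)
    if model.base == "SC":
        breaks.add(p["tsc_frac"] * ts)
    if model.growth:
        breaks.update(ts * i / _N_GROWTH_STEPS for i in range(1, _N_GROWTH_STEPS))
    grid = np.array(sorted(breaks))
    ends, nu1s, nu2s, m12s, m21s = [], [], [], [], []
    for a, b in zip(grid[:-1], grid[1:]):
        mid = 0.5 * (a + b)
        if model.growth:
            nu1 = p["nu1"] * p["r1"] ** (mid / ts)
            nu2 = p["nu2"] * p["r2"] ** (mid / ts)
        else:
            nu1, nu2 = p["nu1"], p["nu2"]
        if model.base == "IM":
            mig = True
        elif model.base == "AM":
            mig = mid >= p["tam_frac"] * ts
        elif model.base == "SC":
            mig = mid <= p["tsc_frac"] * ts
        else:
            mig = False
        m12 = p.get("m12", 0.0) * mig_factor if mig else 0.0
        m21 = p.get("m21", 0.0) * mig_factor if mig else 0.0
        ends.append(b)
        nu1s.append(nu1 * size_factor)
        nu2s.append(nu2 * size_factor)
        m12s.append(m12)
        m21s.append(m21)
    return (
        np.array(ends),
        np.array(nu1s),
        np.array(nu2s),
        np.array(m12s),
        np.array(m21s),
        p["na"] * size_factor,
    )


def _check_params(model: DemographicModel, params: dict) -> dict:
    missing = [k for k in model.param_names if k not in params]
    if missing:
        raise ValueError(f"model {model.name}: missing parameters {missing}")
    for k, (lo, hi) in model.bounds.items():
        if not (lo <= params[k] <= hi):
            raise ValueError(
                f"model {model.name}: {k}={params[k]} outside [{lo}, {hi}]"
            )
    return {k: float(params[k]) for k in params}


def expected_branch_sfs(
    model: DemographicModel,
    params: dict,
    n1h: int,
    n2h: int,
    n_reps: int,
    seed: int,
) -> np.ndarray:
    """Mean branch length subtending (i, j), mixed over locus classes.

    Multiply by theta/2 (per locus) for the expected per-locus jSFS.
    Each locus class is re-seeded deterministically, giving common
    random numbers across parameter evaluations.
    """
    params = _check_params(model, params)
    out_total = np.zeros((n1h + 1, n2h + 1))
    for ci, (w, over) in enumerate(_locus_classes(model, params)):
        if w <= 0:
            continue
        eps = _epoch_arrays(model, params, **over)
        _coalescent.seed_engine(int(seed) + 7919 * ci)
        out = np.zeros((n1h + 1, n2h + 1))
        _coalescent.branch_sfs(n1h, n2h, *eps[:5], eps[5], n_reps, out)
        out_total += w * out / n_reps
    return out_total


def expected_jsfs(
    model,
    params: dict,
    n1: int,
    n2: int,
    n_loci: int,
    seed: int,
    theta: float = 1.0,
    folded: bool = False,
    n_reps: int | None = None,
) -> JointSFS:
    """Monte-Carlo expected jSFS for ``n_loci`` loci of scaled rate theta.

    ``n1``/``n2`` are diploid sample sizes; ``n_reps`` genealogies
    (default: ``n_loci``) estimate the expected branch lengths.
    """
    if isinstance(model, str):
        model = get_model(model)
    n_reps = int(n_reps or n_loci)
    br = expected_branch_sfs(model, params, 2 * n1, 2 * n2, n_reps, seed)
    counts = 0.5 * theta * n_loci * br
    s = JointSFS(counts, folded=False)
    return s.fold() if folded else s


def simulate_sites(
    model,
    params: dict,
    n1: int,
    n2: int,
    n_loci: int,
    seed: int,
    theta: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Infinite-sites data: (mask1, mask2, locus) arrays for each SNP.

    Bitmask bit h of mask1 flags haploid copy h of population 1 as a
    carrier of the derived allele.  Diploid sample sizes up to 31 per
    population (62 haploids per int64 mask).
    """
    if isinstance(model, str):
        model = get_model(model)
    params = _check_params(model, params)
    if n1 > 31 or n2 > 31:
        raise ValueError("at most 31 diploid individuals per population")
    if n_loci <= 0:
        raise ValueError("n_loci must be positive")
    rng = np.random.default_rng(seed)
    classes = _locus_classes(model, params)
    weights = np.array([w for w, _ in classes])
    class_of = rng.choice(len(classes), size=n_loci, p=weights / weights.sum())
    masks1, masks2, loci = [], [], []
    for ci, (_, over) in enumerate(classes):
        nl = int((class_of == ci).sum())
        if nl == 0:
            continue
        locus_ids = np.flatnonzero(class_of == ci)
        eps = _epoch_arrays(model, params, **over)
        cap = max(10_000, int(n_loci * (1.0 + theta * 30.0)))
        m1 = np.zeros(cap, dtype=np.int64)
        m2 = np.zeros(cap, dtype=np.int64)
        lo = np.zeros(cap, dtype=np.int64)
        _coalescent.seed_engine(int(rng.integers(2**31 - 1)))
        ns = _coalescent.mutation_sites(
            2 * n1, 2 * n2, *eps[:5], eps[5], 0.5 * theta, nl, m1, m2, lo
        )
        masks1.append(m1[:ns])
        masks2.append(m2[:ns])
        loci.append(locus_ids[lo[:ns]])
    mask1 = np.concatenate(masks1) if masks1 else np.zeros(0, np.int64)
    mask2 = np.concatenate(masks2) if masks2 else np.zeros(0, np.int64)
    locus = np.concatenate(loci) if loci else np.zeros(0, np.int64)
    order = np.argsort(locus, kind="stable")
    return mask1[order], mask2[order], locus[order]


# ------------------------------------------------------------- fitting

@dataclass
class FitResult:
    """Best fit of one scenario to an observed jSFS."""

    model: DemographicModel
    params: dict[str, float]
    theta_hat: float
    loglik: float
    n_fits: int
    seed: int | None = None
    stronger: bool | None = field(default=None)
    fixed: dict[str, float] = field(default_factory=dict)

    @property
    def k(self) -> int:
        """Free parameters: fitted scaled parameters plus theta_hat."""
        return len(self.model.param_names) - len(self.fixed) + 1

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.loglik

    def to_biological(
        self, mu: float, seq_length: float, generation_time: float = 4.0
    ) -> dict[str, float]:
        return to_biological(
            self.model, self.params, self.theta_hat, mu, seq_length, generation_time
        )

    def summary(self) -> str:
        lines = [
            f"Demographic fit: {self.model.name}",
            f"  composite log-likelihood {self.loglik:.3f}",
            f"  k = {self.k} free parameters, AIC = {self.aic:.3f}",
            f"  theta_hat (spectrum scale) = {self.theta_hat:.6g}",
            "  scaled parameters:",
        ]
        for name in self.model.param_names:
            tag = "  (fixed)" if name in self.fixed else ""
            lines.append(f"    {name:>9s} = {self.params[name]:.6g}{tag}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "model": self.model.name,
            "params": self.params,
            "theta_hat": self.theta_hat,
            "loglik": self.loglik,
            "k": self.k,
            "aic": self.aic,
        }


def _poisson_loglik(obs: np.ndarray, model: np.ndarray, mask: np.ndarray) -> float:
    o = obs[mask]
    e = np.maximum(model[mask], 1e-12)
    return float(np.sum(o * np.log(e) - e - gammaln(o + 1.0)))


class JointSFSModel:
    """Composite-likelihood model of an observed jSFS under one scenario.

    Parameters
    ----------
    obs
        Observed spectrum (folded spectra are fitted with folded
        expectations).
    scenario
        A :class:`DemographicModel` or its name.
    n_reps
        Genealogies per likelihood evaluation.  Common random numbers
        (a fixed engine seed per instance) keep the Monte-Carlo surface
        smooth across evaluations.
    fixed
        Parameters held at given values and excluded from the free
        count k.  Because theta is profiled out, rescaling all sizes
        and times (and inversely the migration rates) is an exact
        likelihood ridge; the default anchors the ancestral size
        ``na = 1`` so sizes are relative to the ancestral population.
        Pass ``fixed={}`` to fit ``na`` too.
    """

    def __init__(
        self,
        obs: JointSFS,
        scenario: DemographicModel | str,
        n_reps: int = 1500,
        engine_seed: int = 1,
        fixed: dict[str, float] | None = None,
    ) -> None:
        self.obs = obs
        self.scenario = get_model(scenario) if isinstance(scenario, str) else scenario
        self.n_reps = int(n_reps)
        self.engine_seed = int(engine_seed)
        if fixed is None:
            fixed = {"na": 1.0}
        self.fixed = {
            k: float(v) for k, v in fixed.items() if k in self.scenario.param_names
        }
        self.free_names = [
            n for n in self.scenario.param_names if n not in self.fixed
        ]
        self._mask = obs.mask()
        self._obs_sum = float(obs.counts[self._mask].sum())

    _N_BATCH = 8

    def _expected(self, params: dict) -> tuple[np.ndarray, np.ndarray]:
        """(mean, variance-of-mean) of the expected spectrum.

        The engine runs in fixed-seed batches; the batch variance feeds
        the Monte-Carlo bias correction of the likelihood.
        """
        reps_per = max(1, self.n_reps // self._N_BATCH)
        batches = []
        for b in range(self._N_BATCH):
            br = expected_branch_sfs(
                self.scenario,
                params,
                self.obs.n1,
                self.obs.n2,
                reps_per,
                self.engine_seed + 104729 * b,
            )
            if self.obs.folded:
                br = _fold_array(br)
            batches.append(br)
        B = np.array(batches)
        return B.mean(axis=0), B.var(axis=0, ddof=1) / self._N_BATCH

    def loglik(self, params: dict) -> tuple[float, float]:
        """(composite log-likelihood, profiled scale theta_hat).

        The Monte-Carlo estimate of each expected cell enters through
        log(e); by Jensen this penalises high-variance (e.g. migration-
        rich) histories, so the first-order bias obs * Var(e)/(2 e^2)
        is added back using the batch variance.
        """
        e, var = self._expected(params)
        esum = float(e[self._mask].sum())
        if not np.isfinite(esum) or esum <= 0:
            return -np.inf, np.nan
        theta_hat = self._obs_sum / esum
        eh = np.maximum(theta_hat * e, 1e-12)
        raw = _poisson_loglik(self.obs.counts, eh, self._mask)
        correction = float(
            np.sum(
                self.obs.counts[self._mask]
                * (theta_hat**2 * var[self._mask])
                / (2.0 * eh[self._mask] ** 2)
            )
        )
        return raw + correction, theta_hat

    # -- three-step optimisation ------------------------------------
    def _vec_to_params(self, x: np.ndarray) -> dict:
        b = self.scenario.bounds
        out = dict(self.fixed)
        for name, xi in zip(self.free_names, x):
            lo, hi = b[name]
            out[name] = float(np.clip(np.exp(xi), lo, hi))
        return out

    def _objective(self, x: np.ndarray) -> float:
        ll, _ = self.loglik(self._vec_to_params(x))
        return -ll

    def fit(
        self,
        n_fits: int = 20,
        seed: int | None = None,
        de_maxiter: int = 35,
        de_popsize: int = 10,
        maxiter: int = 300,
        polish_factor: int = 5,
    ) -> FitResult:
        """Best of ``n_fits`` replicate three-step optimisations.

        Each replicate runs (1) a broad population-based random search
        over log-uniform bounds (differential evolution), (2)
        Nelder–Mead refinement from its best point and (3) a
        perturbation restart.  The overall best point is finally
        polished with ``polish_factor`` more genealogies per evaluation
        to shrink the Monte-Carlo error of the reported optimum.
        """
        names = self.free_names
        lo = np.log([self.scenario.bounds[n][0] for n in names])
        hi = np.log([self.scenario.bounds[n][1] for n in names])
        nm_opts = {"maxfev": maxiter, "xatol": 1e-3, "fatol": 1e-2}
        ss = np.random.SeedSequence(seed)
        best_x, best_f = None, np.inf
        for child in ss.spawn(n_fits):
            rng = np.random.default_rng(child)
            # step 1: broad population-based random search within bounds
            de = differential_evolution(
                self._objective,
                list(zip(lo, hi)),
                seed=int(rng.integers(2**31 - 1)),
                maxiter=de_maxiter,
                popsize=de_popsize,
                tol=0.01,
                init="sobol",
                polish=False,
            )
            # step 2: derivative-free local refinement
            res = minimize(self._objective, de.x, method="Nelder-Mead", options=nm_opts)
            x1, f1 = (res.x, res.fun) if res.fun < de.fun else (de.x, de.fun)
            # step 3: perturbation restart around the refined optimum
            xp = np.clip(x1 + rng.normal(0.0, 0.25, size=len(names)), lo, hi)
            res2 = minimize(self._objective, xp, method="Nelder-Mead", options=nm_opts)
            if res2.fun < f1:
                x1, f1 = res2.x, res2.fun
            if f1 < best_f:
                best_x, best_f = x1, f1
        if best_x is None or not np.isfinite(best_f):
            raise RuntimeError(
                f"all {n_fits} fits of {self.scenario.name} were non-finite; "
                "check the observed spectrum and bounds"
            )
        polished = JointSFSModel(
            self.obs,
            self.scenario,
            n_reps=self.n_reps * max(1, polish_factor),
            engine_seed=self.engine_seed,
            fixed=self.fixed,
        )
        res = minimize(
            polished._objective,
            best_x,
            method="Nelder-Mead",
            options={"maxfev": max(150, maxiter // 2), "xatol": 1e-3, "fatol": 1e-2},
        )
        if np.isfinite(res.fun):
            best_x = res.x
        params = self._vec_to_params(best_x)
        ll, theta_hat = polished.loglik(params)
        return FitResult(
            model=self.scenario,
            params=params,
            theta_hat=theta_hat,
            loglik=ll,
            n_fits=n_fits,
            seed=seed,
            fixed=dict(self.fixed),
        )


def fit_model(
    obs: JointSFS,
    model: DemographicModel | str,
    n_fits: int = 20,
    seed: int | None = None,
    n_reps: int = 1500,
    fixed: dict[str, float] | None = None,
    **kwargs,
) -> FitResult:
    """Fit one scenario to an observed jSFS (see :class:`JointSFSModel`)."""
    return JointSFSModel(obs, model, n_reps=n_reps, fixed=fixed).fit(
        n_fits=n_fits, seed=seed, **kwargs
    )


def compare_models(fits: list[FitResult], delta: float = 10.0) -> pd.DataFrame:
    """Rank fits by AIC; flag a fit 'stronger' iff its AIC beats every
    competitor by more than ``delta`` (the conservative dAIC < -10 rule)."""
    if not fits:
        raise ValueError("need at least one fit")
    rows = []
    aics = np.array([f.aic for f in fits])
    for f in fits:
        others = [a for a in aics if a != f.aic] or [np.inf]
        stronger = bool(f.aic <= min(others) - delta) if len(fits) > 1 else False
        f.stronger = stronger
        rows.append(
            {
                "model": f.model.name,
                "k": f.k,
                "loglik": f.loglik,
                "AIC": f.aic,
                "dAIC": f.aic - aics.min(),
                "stronger": stronger,
            }
        )
    return (
        pd.DataFrame(rows).sort_values("AIC", kind="stable").reset_index(drop=True)
    )


# ------------------------------------------------------ unit conversion

_TIME_PARAMS = ("ts",)
_SIZE_PARAMS = ("nu1", "nu2", "na")
_MIG_PARAMS = ("m12", "m21")


def to_biological(
    model: DemographicModel,
    params: dict,
    theta_hat: float,
    mu: float,
    seq_length: float,
    generation_time: float = 4.0,
) -> dict[str, float]:
    """Scaled parameters -> biological units.

    N_ref = theta_hat / (4 mu L); sizes become individuals, times become
    years (time unit 2 N_ref generations x generation time), migration
    becomes per-generation rates m = M / (2 N_ref).
    """
    nref = theta_hat / (4.0 * mu * seq_length)
    out = {"N_ref": nref}
    for k, v in params.items():
        if k in _SIZE_PARAMS:
            out["N" + k[2:] if k.startswith("nu") else "N_anc"] = v * nref
        elif k in _TIME_PARAMS:
            out["T" + k[1:] + "_years"] = v * 2.0 * nref * generation_time
        elif k in _MIG_PARAMS:
            out[k + "_per_gen"] = v / (2.0 * nref)
        else:
            out[k] = v
    if "tam_frac" in params:
        out["Tam_years"] = params["tam_frac"] * params["ts"] * 2 * nref * generation_time
    if "tsc_frac" in params:
        out["Tsc_years"] = params["tsc_frac"] * params["ts"] * 2 * nref * generation_time
    return out


def to_scaled(
    bio: dict[str, float],
    theta_hat: float,
    mu: float,
    seq_length: float,
    generation_time: float = 4.0,
) -> dict[str, float]:
    """Inverse of :func:`to_biological` for the shared keys."""
    nref = theta_hat / (4.0 * mu * seq_length)
    out = {}
    for k, v in bio.items():
        if k == "N_ref":
            continue
        if k == "N_anc":
            out["na"] = v / nref
        elif k.startswith("N") and not k.endswith("_years"):
            out["nu" + k[1:]] = v / nref
        elif k.endswith("_years") and k.startswith("Ts"):
            out["ts"] = v / (2.0 * nref * generation_time)
        elif k.endswith("_per_gen"):
            out[k[: -len("_per_gen")]] = v * 2.0 * nref
        else:
            out[k] = v
    return out
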