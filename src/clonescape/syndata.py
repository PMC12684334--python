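"""Synthetic inputs with known truth for every pipeline stage.

Generators emulate the study system: sampling sites where genets
(genetic individuals) are re-sampled as multiple ramets with genotyping
error and missing calls; hierarchically structured metapopulations with
a target F_ST; pairs of populations diverged under SI/IM/AM/SC
histories; advective dispersal along a 1-D coastline; and
lineage-structured morphometric traits.  Every generator is a pure
function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import demography
from .genio import MISSING, SNPMatrix


@dataclass
class ClonalSiteTruth:
    """Ground truth behind a simulated partially clonal site."""

    genet_of_individual: dict[str, str]
    clonal_fraction: float
    error_rate: float
    missing_rate: float
    seed: int

    @property
    def R(self) -> float:
        """Clonal richness (G-1)/(N-1) of the truth partition."""
        N = len(self.genet_of_individual)
        G = len(set(self.genet_of_individual.values()))
        return (G - 1) / (N - 1) if N > 1 else np.nan

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            sorted(self.genet_of_individual.items()),
            columns=["individual_id", "genet"],
        ).to_csv(path, sep="\t", index=False)


@dataclass
class MetapopConfig:
    """Settings for a Balding–Nichols structured metapopulation."""

    n_demes: int
    fst_target: float
    n_per_deme: int
    n_loci: int
    ancestral_freq_low: float = 0.05
    ancestral_freq_high: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.fst_target < 1):
            raise ValueError("fst_target must be in [0, 1)")
        if self.n_demes < 1 or self.n_per_deme < 1 or self.n_loci < 1:
            raise ValueError("counts must be positive")


@dataclass
class DispersalMatrix:
    """Row-stochastic per-generation dispersal matrix on habitat sites."""

    P: np.ndarray
    habitat: np.ndarray
    site_labels: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        self.habitat = np.asarray(self.habitat, dtype=bool)
        if self.P.ndim != 2 or self.P.shape[0] != self.P.shape[1]:
            raise ValueError("P must be square")
        if (self.P < 0).any():
            raise ValueError("P entries must be >= 0")
        rows = self.P[self.habitat].sum(axis=1)
        if rows.size and not np.allclose(rows, 1.0, atol=1e-9):
            raise ValueError("habitat rows of P must sum to 1")
        if not self.site_labels:
            self.site_labels = [f"s{i + 1}" for i in range(self.P.shape[0])]

    @property
    def n(self) -> int:
        return self.P.shape[0]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.P, index=self.site_labels, columns=self.site_labels).to_csv(
            path, sep="\t"
        )

    @classmethod
    def from_tsv(cls, path, habitat=None) -> "DispersalMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        P = df.to_numpy(dtype=float)
        if habitat is None:
            habitat = P.sum(axis=1) > 0
        return cls(P, habitat, [str(c) for c in df.columns])


@dataclass
class MorphoTable:
    """Morphometric traits (FW, DBD, UX); three branch measurements each.

    ``individuals`` holds the per-individual trait means used by the
    analyses; ``branches`` the underlying branch-level measurements.
    """

    individuals: pd.DataFrame
    branches: pd.DataFrame

    TRAITS = ("FW", "DBD", "UX")

    def to_csv(self, path) -> None:
        self.individuals.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "MorphoTable":
        ind = pd.read_csv(path)
        return cls(ind, pd.DataFrame(columns=["individual_id", "branch", *cls.TRAITS]))


# --------------------------------------------------------------- clonal

def sim_clonal_site(
    n_genets: int,
    ramets_per_genet: list[int] | int,
    n_loci: int,
    error_rate: float = 0.0,
    missing_rate: float = 0.0,
    seed: int = 0,
    site: str = "site1",
    freq_low: float = 0.05,
    freq_high: float = 0.95,
) -> tuple[SNPMatrix, ClonalSiteTruth]:
    """Simulate one partially clonal site.

    Genet genotypes are drawn from per-locus allele frequencies
    Uniform(freq_low, freq_high); each ramet copies its genet's genotype
    with independent per-allele flips at ``error_rate`` (so replicate
    discordance has a closed form) and completely-at-random masking at
    ``missing_rate``.
    """
    if n_genets < 1:
        raise ValueError("n_genets must be >= 1")
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    for r, nm in ((error_rate, "error_rate"), (missing_rate, "missing_rate")):
        if not (0 <= r < 1):
            raise ValueError(f"{nm} must be in [0, 1)")
    if isinstance(ramets_per_genet, (int, np.integer)):
        ramets_per_genet = [int(ramets_per_genet)] * n_genets
    if len(ramets_per_genet) != n_genets:
        raise ValueError("ramets_per_genet must have n_genets entries")
    if min(ramets_per_genet) < 1:
        raise ValueError("each genet needs at least one ramet")
    rng = np.random.default_rng(seed)
    p = rng.uniform(freq_low, freq_high, size=n_loci)
    # genet genotypes as two allele draws so per-allele errors are natural
    genet_alleles = rng.random((n_genets, n_loci, 2)) < p[None, :, None]
    rows, ind_ids, genet_of = [], [], {}
    for g in range(n_genets):
        for r in range(ramets_per_genet[g]):
            ind = f"{site}_g{g + 1:03d}_r{r + 1:02d}"
            alleles = genet_alleles[g].copy()
            if error_rate > 0:
                flips = rng.random(alleles.shape) < error_rate
                alleles = alleles ^ flips
            dos = alleles.sum(axis=1).astype(np.int16)
            if missing_rate > 0:
                dos[rng.random(n_loci) < missing_rate] = MISSING
            rows.append(dos)
            ind_ids.append(ind)
            genet_of[ind] = f"genet{g + 1:03d}"
    N = len(ind_ids)
    G = n_genets
    clonal_fraction = 1.0 - (G - 1) / (N - 1) if N > 1 else 1.0
    m = SNPMatrix(
        np.vstack(rows),
        ind_ids,
        [site] * N,
        [f"L{j + 1:05d}" for j in range(n_loci)],
    )
    return m, ClonalSiteTruth(genet_of, clonal_fraction, error_rate, missing_rate, seed)


# ---------------------------------------------------------- metapopulation

def sim_metapopulation(cfg: MetapopConfig) -> SNPMatrix:
    """Balding–Nichols metapopulation with a target F_ST.

    Deme allele frequencies are Beta-distributed around ancestral
    frequencies with dispersion set by ``fst_target``; genotypes are
    Binomial(2, p_deme).  ``fst_target = 0`` gives identical deme
    frequencies.
    """
    rng = np.random.default_rng(cfg.seed)
    p_anc = rng.uniform(cfg.ancestral_freq_low, cfg.ancestral_freq_high, cfg.n_loci)
    F = cfg.fst_target
    dosages = np.empty((cfg.n_demes * cfg.n_per_deme, cfg.n_loci), dtype=np.int16)
    ind_ids, sites = [], []
    for d in range(cfg.n_demes):
        if F == 0:
            p_d = p_anc
        else:
            a = p_anc * (1 - F) / F
            b = (1 - p_anc) * (1 - F) / F
            p_d = rng.beta(a, b)
        block = rng.binomial(2, p_d, size=(cfg.n_per_deme, cfg.n_loci))
        dosages[d * cfg.n_per_deme : (d + 1) * cfg.n_per_deme] = block
        site = f"deme{d + 1:02d}"
        for i in range(cfg.n_per_deme):
            ind_ids.append(f"{site}_i{i + 1:03d}")
            sites.append(site)
    return SNPMatrix(
        dosages, ind_ids, sites, [f"L{j + 1:05d}" for j in range(cfg.n_loci)]
    )


# ------------------------------------------------------------- divergence

def sim_divergence(
    model,
    params: dict,
    n1: int,
    n2: int,
    n_loci: int,
    seed: int,
    theta: float = 1.0,
) -> tuple[SNPMatrix, demography.JointSFS]:
    """Two-population divergence data under an SI/IM/AM/SC history.

    ``n1``/``n2`` diploid individuals are sampled from the two
    populations; ``n_loci`` unlinked loci of scaled mutation rate
    ``theta`` are simulated with the structured-coalescent engine and
    every segregating site becomes one matrix column.  The returned
    unfolded jSFS equals ``build_jsfs`` applied to the returned matrix.
    """
    mask1, mask2, locus = demography.simulate_sites(
        model, params, n1, n2, n_loci, seed, theta=theta
    )
    ns = mask1.size
    dos = np.zeros((n1 + n2, ns), dtype=np.int16)
    for s in range(ns):
        for i in range(n1):
            dos[i, s] = ((mask1[s] >> (2 * i)) & 1) + ((mask1[s] >> (2 * i + 1)) & 1)
        for i in range(n2):
            dos[n1 + i, s] = ((mask2[s] >> (2 * i)) & 1) + (
                (mask2[s] >> (2 * i + 1)) & 1
            )
    ind_ids = [f"pop1_i{i + 1:03d}" for i in range(n1)] + [
        f"pop2_i{i + 1:03d}" for i in range(n2)
    ]
    sites = ["pop1"] * n1 + ["pop2"] * n2
    loci = [f"L{locus[s] + 1:06d}_s{s + 1:06d}" for s in range(ns)]
    m = SNPMatrix(dos, ind_ids, sites, loci)
    sfs = demography.build_jsfs(m, {"pop1"}, {"pop2"})
    return m, sfs


# -------------------------------------------------------------- dispersal

def sim_dispersal(
    n_sites: int,
    advection: float = 0.0,
    diffusion: float = 1.0,
    habitat_mask: list[bool] | None = None,
    seed: int = 0,
) -> DispersalMatrix:
    """Advective dispersal kernel on a 1-D coastline.

    Propagules released at site i land around i + ``advection`` (sites
    downstream for positive advection) with Gaussian spread
    ``diffusion``; mass beyond the coastline ends is reflected back, so
    the unmasked kernel is symmetric when advection is zero.  Sites
    outside ``habitat_mask`` neither emit nor receive; remaining rows
    are renormalised.
    """
    if n_sites < 2:
        raise ValueError("need at least two sites")
    if diffusion <= 0:
        raise ValueError("diffusion must be > 0")
    if habitat_mask is None:
        habitat_mask = [True] * n_sites
    habitat = np.asarray(habitat_mask, dtype=bool)
    if habitat.size != n_sites:
        raise ValueError("habitat_mask length must equal n_sites")
    if not habitat.any():
        raise ValueError("habitat_mask must keep at least one site")
    idx = np.arange(n_sites)
    # reflected discretised Gaussian kernel
    P = np.zeros((n_sites, n_sites))
    images = [lambda j: j, lambda j: -1 - j, lambda j: 2 * n_sites - 1 - j]
    for i in range(n_sites):
        for img in images:
            jj = img(idx)
            P[i] += np.exp(-((jj - i - advection) ** 2) / (2 * diffusion**2))
    P /= P.sum(axis=1, keepdims=True)
    # habitat masking, then row renormalisation over habitat columns
    P[~habitat, :] = 0.0
    P[:, ~habitat] = 0.0
    rows = P.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(rows > 0, P / rows, 0.0)
    return DispersalMatrix(
        P,
        habitat,
        [f"s{i + 1}" for i in range(n_sites)],
        {"advection": advection, "diffusion": diffusion, "seed": seed},
    )


# ------------------------------------------------------------------ morpho

def sim_morpho(
    lineage_means: dict[str, tuple[float, float, float]],
    n_per_lineage: int,
    noise_sd: tuple[float, float, float] = (0.0, 0.0, 0.0),
    seed: int = 0,
    site_of_lineage: dict[str, str] | None = None,
) -> MorphoTable:
    """Lineage-structured morphometric traits.

    Per individual and trait, three branch-level measurements are drawn
    Normal(lineage mean, sd) and averaged — mirroring field protocols
    that average three branches per thallus.  UX means must be >= 1 (a
    flat margin has UX = 1); draws are floored at 1.
    """
    sds = np.asarray(noise_sd, dtype=float)
    if (sds < 0).any():
        raise ValueError("noise_sd must be >= 0")
    for lin, means in lineage_means.items():
        if means[2] < 1:
            raise ValueError(f"lineage {lin}: UX mean must be >= 1")
    rng = np.random.default_rng(seed)
    ind_rows, branch_rows = [], []
    for lin, means in lineage_means.items():
        site = (site_of_lineage or {}).get(lin, lin)
        for i in range(n_per_lineage):
            ind = f"{lin}_i{i + 1:03d}"
            vals = {}
            for t, trait in enumerate(MorphoTable.TRAITS):
                draws = rng.normal(means[t], sds[t], size=3)
                if trait == "UX":
                    draws = np.maximum(draws, 1.0)
                for b, v in enumerate(draws):
                    branch_rows.append(
                        {
                            "individual_id": ind,
                            "branch": b + 1,
                            "trait": trait,
                            "value": v,
                        }
                    )
                vals[trait] = float(draws.mean())
            ind_rows.append(
                {"individual_id": ind, "site": site, "lineage": lin, **vals}
            )
    branches = (
        pd.DataFrame(branch_rows)
        .pivot(index=["individual_id", "branch"], columns="trait", values="value")
        .reset_index()[["individual_id", "branch", *MorphoTable.TRAITS]]
    )
    return MorphoTable(pd.DataFrame(ind_rows), branches)
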