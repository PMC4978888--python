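"""Synthetic germplasm collection generator.

Emulates the statistical structure of a large, historically phenotyped
soybean germplasm collection: ~9 genetic clusters of fully inbred lines
(Balding-Nichols differentiated allele frequencies with Dirichlet
admixture emitted as a membership table), maturity groups correlated with
cluster, 25 trials across 3 states whose maturity-group composition
respects latitude bands (no trial mixes the earliest and latest groups),
most accessions evaluated in a single trial, heritable oil / protein /
yield with trial and MG-within-trial effects plus trial-specific G x E,
and lodging / shattering scores on 1-5 scales that mechanically reduce
machine-harvest yield so the pooled within-trial correlations sit near
-0.21 (lodging) and -0.27 (shattering).

The penalty coefficients ``gamma`` are solved in closed form from those
target correlations (independent latents, Var = 2 for five equiprobable
score classes), not tuned: with targets a, b and within-trial non-penalty
standard deviation s0, D = s0 / sqrt(1 - a^2 - b^2) and
``gamma = target * D / sqrt(2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, MembershipTable, validate_phenotypes
from .exceptions import ValidationError

TRAITS = ("oil", "protein", "yield")


@dataclass
class TraitSpec:
    """Per-trait scale: observed mean, phenotypic SD and heritability."""

    mean: float
    sd: float
    h2: float


@dataclass
class SimulationConfig:
    n_accessions: int = 1000
    p_markers: int = 2000
    n_clusters: int = 9
    fst: float = 0.15
    n_trials: int = 25
    n_states: int = 3
    mg_levels: int = 10
    architecture: str = "infinitesimal"   # or "sparse"
    n_qtl: int = 20
    traits: dict = field(default_factory=lambda: {
        "oil": TraitSpec(19.0, 2.0, 0.7),
        "protein": TraitSpec(42.0, 3.0, 0.7),
        # machine-harvest yield: the lowest-heritability trait of the three
        # in unreplicated historical evaluations
        "yield": TraitSpec(2.2, 0.5, 0.35),
    })
    trial_effect_sd: float = 0.6    # in phenotypic-SD units
    mg_effect_sd: float = 0.4
    gxe_sd: float = 0.35
    # shattering is a genetically simple, highly heritable trait in
    # unimproved landraces (major-locus control); lodging somewhat less so
    lodging_h2: float = 0.75
    shattering_h2: float = 0.85
    gamma_lodging: float | str = "auto"
    gamma_shattering: float | str = "auto"
    target_cor_lodging: float = -0.21
    target_cor_shattering: float = -0.27
    harvest_noise_sd: float = 0.1   # extra machine-harvest noise, SD units
    frac_two_trials: float = 0.15
    missing_rate: float = 0.0
    outbred: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.fst < 1.0):
            raise ValidationError("fst must lie in (0, 1)")
        if self.architecture not in ("infinitesimal", "sparse"):
            raise ValidationError(f"unknown architecture {self.architecture!r}")
        if self.n_qtl > self.p_markers:
            raise ValidationError("n_qtl cannot exceed p_markers")
        for name, t in self.traits.items():
            if not (0.0 <= t.h2 <= 1.0):
                raise ValidationError(f"h2 for {name} outside [0, 1]")
            if t.h2 + self.gxe_sd**2 > 1.0:
                raise ValidationError(
                    f"h2 infeasible for {name}: h2 + gxe_sd^2 exceeds the phenotypic variance"
                )
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValidationError("missing_rate must lie in [0, 1)")


@dataclass
class SyntheticTruth:
    """Ground truth stored alongside generated data for recovery tests."""

    marker_effects: dict      # trait -> length-p effect vector b
    genetic_values: pd.DataFrame  # accession x trait, g_i = sum_l x_il b_l exactly
    cluster_labels: pd.Series
    maturity_group: pd.Series
    h2: dict
    trial_effects: dict       # trait -> {trial: e_j}
    mg_effects: dict          # trait -> {(trial, mg): m_k(j)}


# ------------------------------------------------------------------ genotypes
def simulate_genotypes(cfg: SimulationConfig, rng: np.random.Generator | None = None):
    """Structured genotypes: returns (GenotypeMatrix, cluster labels, MembershipTable).

    Ancestral frequencies are Uniform(0.05, 0.95); cluster frequencies
    follow the Balding-Nichols beta model at differentiation ``fst``; fully
    inbred accessions carry dosage 0 or 2 with P(2) equal to the
    accession's admixture-weighted frequency.  Admixture proportions are
    Dirichlet with a dominant home cluster.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n, p, K, F = cfg.n_accessions, cfg.p_markers, cfg.n_clusters, cfg.fst
    theta_anc = rng.uniform(0.05, 0.95, size=p)
    a = theta_anc * (1.0 - F) / F
    b = (1.0 - theta_anc) * (1.0 - F) / F
    cluster_freq = rng.beta(a, b, size=(K, p))

    home = rng.integers(0, K, size=n)
    alpha = np.full((n, K), 0.3)
    alpha[np.arange(n), home] = 15.0
    q = rng.dirichlet(np.ones(K), size=n)  # placeholder shape; filled row-wise below
    for i in range(n):
        q[i] = rng.dirichlet(alpha[i])
    freqs = q @ cluster_freq  # accession-specific allele frequency per marker

    if cfg.outbred:
        dosages = rng.binomial(2, freqs).astype(float)
    else:
        dosages = 2.0 * (rng.random((n, p)) < freqs)
    if cfg.missing_rate > 0:
        mask = rng.random((n, p)) < cfg.missing_rate
        dosages[mask] = np.nan

    ids = [f"PI{i + 1:06d}" for i in range(n)]
    marker_ids = [f"snp{j + 1:05d}" for j in range(p)]
    g = GenotypeMatrix(ids, marker_ids, dosages).with_theta()
    clusters = pd.Series((home + 1).astype(str), index=ids, name="cluster")
    membership = MembershipTable(ids, q / q.sum(axis=1, keepdims=True))
    return g, clusters, membership


def assign_maturity_groups(cfg: SimulationConfig, clusters: pd.Series,
                           rng: np.random.Generator) -> pd.Series:
    """MG labels 0..mg_levels-1 correlated with cluster (clusters occupy
    staggered latitude niches)."""
    K = cfg.n_clusters
    centers = np.linspace(0, cfg.mg_levels - 1, K)
    c_idx = clusters.astype(int).to_numpy() - 1
    mg = np.clip(
        np.round(rng.normal(centers[c_idx], 1.2)), 0, cfg.mg_levels - 1
    ).astype(int)
    return pd.Series(mg, index=clusters.index, name="maturity_group")


# --------------------------------------------------------------- trial design
def _state_bands(cfg: SimulationConfig) -> list[tuple[int, int]]:
    """Contiguous, slightly overlapping MG bands, north to south."""
    edges = np.linspace(0, cfg.mg_levels - 1, cfg.n_states + 1)
    bands = []
    for s in range(cfg.n_states):
        lo = int(np.floor(edges[s]))
        hi = int(np.ceil(edges[s + 1]))
        bands.append((max(lo - (1 if s > 0 else 0), 0), min(hi, cfg.mg_levels - 1)))
    return bands


def simulate_trial_design(cfg: SimulationConfig, mg: pd.Series,
                          rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Assign accessions to 1-2 trials respecting state-MG latitude bands.

    Returns a frame with one row per (accession, trial):
    accession_id, trial_id, state, maturity_group.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    bands = _state_bands(cfg)
    trial_states = np.sort(np.arange(cfg.n_trials) % cfg.n_states)
    trial_ids = [f"T{j + 1:02d}" for j in range(cfg.n_trials)]
    state_names = [f"S{s + 1}" for s in range(cfg.n_states)]
    trials_by_state: dict[int, list[int]] = {}
    for j, s in enumerate(trial_states):
        trials_by_state.setdefault(int(s), []).append(j)
    for s, (lo, hi) in enumerate(bands):
        if s not in trials_by_state:
            raise ValidationError("infeasible design: a state has no trials")

    rows = []
    for acc, m in mg.items():
        candidate_states = [s for s, (lo, hi) in enumerate(bands) if lo <= m <= hi]
        if not candidate_states:
            candidate_states = [int(np.argmin([min(abs(m - lo), abs(m - hi)) for lo, hi in bands]))]
        cand_trials = [j for s in candidate_states for j in trials_by_state[s]]
        k = 2 if (len(cand_trials) > 1 and rng.random() < cfg.frac_two_trials) else 1
        chosen = rng.choice(cand_trials, size=k, replace=False)
        for j in chosen:
            rows.append((acc, trial_ids[j], state_names[trial_states[j]], int(m)))
    return pd.DataFrame(rows, columns=["accession_id", "trial_id", "state", "maturity_group"])


# ---------------------------------------------------------------- phenotypes
def _discretize_latent(latent: np.ndarray) -> np.ndarray:
    """Cut a standardized latent at equiprobable normal thresholds into 1..5."""
    from scipy.stats import norm

    z = (latent - latent.mean()) / latent.std()
    cuts = norm.ppf([0.2, 0.4, 0.6, 0.8])
    return (np.digitize(z, cuts) + 1).astype(int)


def simulate_phenotypes(cfg: SimulationConfig, g: GenotypeMatrix, design: pd.DataFrame,
                        rng: np.random.Generator | None = None):
    """Generate the phenotype table and ground truth for oil, protein, yield.

    Record value = mean + e_j + m_k(j) + g_i + gxe_ij + eps, all scaled to
    the trait's units.  Yield is machine-harvest yield: the genetic yield
    potential minus gamma_L*(lodging-1) + gamma_S*(shattering-1) penalties
    plus harvest noise.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 2)
    ids = g.accession_ids
    n, p = g.n_accessions, g.n_markers
    acc_index = {a: i for i, a in enumerate(ids)}
    X = g.dosages.copy()
    if np.isnan(X).any():
        theta = g.theta if g.theta is not None else g.compute_theta()
        fill = np.broadcast_to(2.0 * theta, X.shape)
        X[np.isnan(X)] = fill[np.isnan(X)]

    rec_acc = design["accession_id"].map(acc_index).to_numpy()
    n_rec = len(design)

    marker_effects: dict = {}
    genetic: dict = {}
    trial_effects: dict = {}
    mg_effects: dict = {}
    h2_out: dict = {}
    values: dict = {}

    def draw_effects(h2: float, sd: float) -> tuple[np.ndarray, np.ndarray]:
        """Marker effects scaled so var(g) = h2 * sd^2 across accessions."""
        b = np.zeros(p)
        if cfg.architecture == "sparse":
            qtl = rng.choice(p, size=cfg.n_qtl, replace=False)
            b[qtl] = rng.normal(0.0, 1.0, size=cfg.n_qtl)
        else:
            b = rng.normal(0.0, 1.0, size=p)
        gv = X @ b
        target_var = h2 * sd**2
        s = np.sqrt(target_var / np.var(gv)) if np.var(gv) > 0 and target_var > 0 else 0.0
        b *= s
        return b, X @ b

    # trial / MG structural effects shared mechanism per trait
    trials = sorted(design["trial_id"].unique())
    cells = sorted(set(zip(design["trial_id"], design["maturity_group"])))
    for trait, tspec in cfg.traits.items():
        b, gv = draw_effects(tspec.h2, tspec.sd)
        marker_effects[trait] = b
        genetic[trait] = gv
        te = {t: rng.normal(0.0, cfg.trial_effect_sd * tspec.sd) for t in trials}
        me = {c: rng.normal(0.0, cfg.mg_effect_sd * tspec.sd) for c in cells}
        trial_effects[trait] = te
        mg_effects[trait] = me
        h2_out[trait] = tspec.h2
        eps_var = (1.0 - tspec.h2 - cfg.gxe_sd**2) * tspec.sd**2
        gxe = rng.normal(0.0, cfg.gxe_sd * tspec.sd, size=n_rec)
        eps = rng.normal(0.0, np.sqrt(eps_var), size=n_rec)
        gc = gv - gv.mean()
        vals = (
            tspec.mean
            + np.array([te[t] for t in design["trial_id"]])
            + np.array([me[c] for c in zip(design["trial_id"], design["maturity_group"])])
            + gc[rec_acc]
            + gxe
            + eps
        )
        values[trait] = vals

    # lodging / shattering latents: heritable, independent of yield genetics
    scores = {}
    for name, h2s in (("lodging", cfg.lodging_h2), ("shattering", cfg.shattering_h2)):
        bs, gvs = draw_effects(h2s, 1.0)
        latent = gvs[rec_acc] + rng.normal(0.0, np.sqrt(max(1.0 - h2s, 1e-12)), size=n_rec)
        scores[name] = _discretize_latent(latent)

    yspec = cfg.traits["yield"]
    s0_sq = (1.0 + cfg.mg_effect_sd**2) * yspec.sd**2 + (cfg.harvest_noise_sd * yspec.sd) ** 2
    a = abs(cfg.target_cor_shattering)
    bcor = abs(cfg.target_cor_lodging)
    D = np.sqrt(s0_sq / (1.0 - a**2 - bcor**2))
    gam_s = a * D / np.sqrt(2.0) if cfg.gamma_shattering == "auto" else float(cfg.gamma_shattering)
    gam_l = bcor * D / np.sqrt(2.0) if cfg.gamma_lodging == "auto" else float(cfg.gamma_lodging)
    harvest_noise = rng.normal(0.0, cfg.harvest_noise_sd * yspec.sd, size=n_rec)
    values["yield"] = (
        values["yield"]
        - gam_l * (scores["lodging"] - 1)
        - gam_s * (scores["shattering"] - 1)
        + harvest_noise
    )

    frames = []
    for trait in cfg.traits:
        frames.append(pd.DataFrame({
            "accession_id": design["accession_id"],
            "trial_id": design["trial_id"],
            "state": design["state"],
            "maturity_group": design["maturity_group"].astype(str),
            "trait": trait,
            "value": values[trait],
            "lodging": scores["lodging"],
            "shattering": scores["shattering"],
        }))
    pheno = validate_phenotypes(pd.concat(frames, ignore_index=True))

    clusters = design.drop_duplicates("accession_id").set_index("accession_id")
    truth = SyntheticTruth(
        marker_effects=marker_effects,
        genetic_values=pd.DataFrame(genetic, index=ids),
        cluster_labels=None,
        maturity_group=clusters["maturity_group"],
        h2=h2_out,
        trial_effects=trial_effects,
        mg_effects=mg_effects,
    )
    return pheno, truth


# --------------------------------------------------------------- convenience
@dataclass
class SyntheticCollection:
    genotypes: GenotypeMatrix
    clusters: pd.Series
    membership: MembershipTable
    design: pd.DataFrame
    phenotypes: pd.DataFrame
    truth: SyntheticTruth
    config: SimulationConfig


def simulate_collection(cfg: SimulationConfig) -> SyntheticCollection:
    """Full generator pipeline from one seed: genotypes, structure, design,
    phenotypes and ground truth."""
    rng = np.random.default_rng(cfg.seed)
    g, clusters, membership = simulate_genotypes(cfg, rng)
    mg = assign_maturity_groups(cfg, clusters, rng)
    design = simulate_trial_design(cfg, mg, rng)
    pheno, truth = simulate_phenotypes(cfg, g, design, rng)
    truth.cluster_labels = clusters
    return SyntheticCollection(g, clusters, membership, design, pheno, truth, cfg)


def scaled_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A desk-scale configuration for quick runs (smaller panel, fewer trials)."""
    base = dict(n_accessions=600, p_markers=800, n_trials=8, seed=seed)
    base.update(overrides)
    return SimulationConfig(**base)
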