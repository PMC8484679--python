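"""Synthetic phylogenies and comparative trait data with known ground truth.

Every downstream stage (index arithmetic, PGLS, imputation, the full
pipeline) is exercised on data generated here, so each generator exposes the
quantities it controls: the tree, the phylogenetic signal lambda, the
cross-trait covariance, the care-to-selection effect, and the missingness
pattern.  Defaults emulate a 64-species comparative dataset of the kind
assembled from the literature for tests of the Darwin-Bateman paradigm:
pure-birth timetree, strong but imperfect phylogenetic signal, log-scale
life-history traits spanning orders of magnitude, roughly 37 of 64 species
exhibiting some parental care, and per-column missing-data fractions between
7% and 48%.

Masking is missing-completely-at-random with exact per-column counts
(round(rate * n)), so tests of the masking contract are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .phylogeny import Phylogeny, lambda_transform
from .trait_indices import hedges_d, ln_cvr

__all__ = [
    "SimulationConfig",
    "MaskedTable",
    "SimulatedDataset",
    "DEFAULT_MISSING_RATES",
    "simulate_tree",
    "simulate_traits",
    "simulate_sex_groups",
    "apply_missingness",
    "simulate_dataset",
]

#: Per-column missing fractions of the emulated 64-species compilation:
#: 31% female body mass, 20% male body mass, 48% testis mass, 36% sperm
#: size, 31% female gamete mass, 27% clutch size, 14% opportunity for
#: selection, 7% opportunity for sexual selection, 23% Bateman gradient.
DEFAULT_MISSING_RATES: dict[str, float] = {
    "female_mass_g": 0.31,
    "male_mass_g": 0.20,
    "testis_mass_g": 0.48,
    "male_gamete_size": 0.36,
    "female_gamete_mass_g": 0.31,
    "clutch_size": 0.27,
    "delta_I": 0.14,
    "delta_I_s": 0.07,
    "delta_beta_ss": 0.23,
}

#: Columns that are never masked: the care variables are not imputed.
PROTECTED_COLUMNS = ("percent_male_care", "has_care", "care_frac", "species")

_LOG_TRAITS = [
    "male_mass_g",
    "female_mass_g",
    "male_gamete_size",
    "female_gamete_mass_g",
    "testis_mass_g",
    "clutch_size",
]
# Root means on the natural-log scale: ~500 g adult masses, sperm-volume
# scale ~50 (arbitrary shared unit), ~1 g eggs, ~5 g testes, ~4 eggs/clutch.
_LOG_ROOT_MEANS = np.array([6.2, 6.2, 3.9, 0.0, 1.6, 1.4])


def _default_trait_cov(n_traits: int, rho: float, rate: float = 1.0) -> np.ndarray:
    R = np.full((n_traits, n_traits), rho * rate)
    np.fill_diagonal(R, rate)
    return R


@dataclass
class SimulationConfig:
    """Knobs of the generative process (tree, traits, effects, missingness)."""

    n_species: int = 64
    tree_model: str = "pure_birth"  # or "coalescent"
    birth_rate: float = 1.0
    trait_covariance: np.ndarray | None = None  # over the log-scale traits
    cross_trait_corr: float = 0.5
    lambda_true: float = 0.8
    root_means: np.ndarray | None = None
    effect_care_on_selection: float = -1.0
    selection_noise_sd: float = 0.3
    p_care: float = 37.0 / 64.0
    missing_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSING_RATES)
    )
    n_auxiliary: int = 0
    aux_observed_cols: Sequence[str] = ("male_mass_g", "female_mass_g", "clutch_size")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 3:
            raise ValueError("n_species must be >= 3")
        if self.tree_model not in ("pure_birth", "coalescent"):
            raise ValueError(f"unknown tree_model {self.tree_model!r}")
        if self.birth_rate < 0:
            raise ValueError("birth_rate must be >= 0")
        if not np.all((0.0 <= np.atleast_1d(self.lambda_true))
                      & (np.atleast_1d(self.lambda_true) <= 1.0)):
            raise ValueError("lambda_true must lie in [0, 1]")
        if self.trait_covariance is None:
            self.trait_covariance = _default_trait_cov(
                len(_LOG_TRAITS), self.cross_trait_corr
            )
        self.trait_covariance = np.asarray(self.trait_covariance, float)
        _check_psd(self.trait_covariance, "trait_covariance")
        if self.root_means is None:
            self.root_means = _LOG_ROOT_MEANS.copy()
        self.root_means = np.asarray(self.root_means, float)
        if self.root_means.shape[0] != self.trait_covariance.shape[0]:
            raise ValueError("root_means length must match trait_covariance size")
        for col, rate in self.missing_rates.items():
            if not (0.0 <= rate < 1.0):
                raise ValueError(f"missing rate for {col!r} must be in [0, 1)")
            if col in PROTECTED_COLUMNS:
                raise ValueError(f"column {col!r} may not be masked")

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        raw = {
            "n_species": self.n_species,
            "tree_model": self.tree_model,
            "birth_rate": self.birth_rate,
            "cross_trait_corr": self.cross_trait_corr,
            "lambda_true": float(np.atleast_1d(self.lambda_true)[0])
            if np.ndim(self.lambda_true) else float(self.lambda_true),
            "effect_care_on_selection": self.effect_care_on_selection,
            "selection_noise_sd": self.selection_noise_sd,
            "p_care": self.p_care,
            "missing_rates": dict(self.missing_rates),
            "n_auxiliary": self.n_auxiliary,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def _check_psd(M: np.ndarray, name: str, tol: float = 1e-8) -> None:
    M = np.asarray(M, float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(M, M.T, rtol=1e-10, atol=1e-12):
        raise ValueError(f"{name} must be symmetric")
    w = np.linalg.eigvalsh(M)
    if w.min() < -tol * max(1.0, w.max()):
        raise ValueError(f"{name} is not positive semi-definite (min eig {w.min():.3g})")


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("start", "children", "end", "label")

    def __init__(self, start: float):
        self.start = start
        self.children: list["_Node"] = []
        self.end: float | None = None
        self.label: str | None = None


def _newick_of(node: _Node, present: float) -> str:
    end = node.end if node.end is not None else present
    length = end - node.start
    if not node.children:
        return f"{node.label}:{length:.12g}"
    inner = ",".join(_newick_of(ch, present) for ch in node.children)
    return f"({inner}):{length:.12g}"


def simulate_tree(
    n_species: int,
    tree_model: str = "pure_birth",
    birth_rate: float = 1.0,
    seed: int = 0,
) -> Phylogeny:
    """Simulate a rooted, binary, ultrametric tree with ``n_species`` tips.

    ``pure_birth`` runs a Yule process forward (per-lineage splitting rate
    ``birth_rate``) with an extra exponential tail after the last split, so
    every pendant edge is strictly positive.  ``coalescent`` builds a
    Kingman coalescent genealogy (rate C(k,2) while k lineages remain);
    ``birth_rate`` then acts as an inverse time scale.  Tips are labelled
    s1..sN; the same seed reproduces the same Newick string byte for byte.
    """
    if n_species < 3:
        raise ValueError("n_species must be >= 3")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    rng = np.random.default_rng(seed)
    if tree_model == "pure_birth":
        root = _Node(0.0)
        root.end = 0.0
        active = [_Node(0.0), _Node(0.0)]
        root.children = list(active)
        t = 0.0
        while len(active) < n_species:
            k = len(active)
            t += rng.exponential(1.0 / (birth_rate * k))
            node = active.pop(int(rng.integers(k)))
            node.end = t
            node.children = [_Node(t), _Node(t)]
            active.extend(node.children)
        present = t + rng.exponential(1.0 / (birth_rate * n_species))
    elif tree_model == "coalescent":
        # Kingman coalescent on backward heights (0 at the tips); the edge
        # above a node has length parent.height - node.height.
        active_ids = list(range(n_species))  # leaf ids
        children: dict[int, tuple[int, int]] = {}
        height_of: dict[int, float] = {i: 0.0 for i in range(n_species)}
        next_id = n_species
        t = 0.0
        while len(active_ids) > 1:
            k = len(active_ids)
            t += rng.exponential(2.0 / (birth_rate * k * (k - 1)))
            i, j = sorted(rng.choice(k, size=2, replace=False))
            a = active_ids.pop(int(j))
            b = active_ids.pop(int(i))
            children[next_id] = (b, a)
            height_of[next_id] = t
            active_ids.append(next_id)
            next_id += 1
        root_id = active_ids[0]
        counter = [0]

        def _nwk(nid: int, parent_h: float) -> str:
            h = height_of[nid]
            length = parent_h - h
            if nid not in children:
                counter[0] += 1
                return f"s{counter[0]}:{length:.12g}"
            left, right = children[nid]
            return f"({_nwk(left, h)},{_nwk(right, h)}):{length:.12g}"

        left, right = children[root_id]
        h_root = height_of[root_id]
        newick = f"({_nwk(left, h_root)},{_nwk(right, h_root)});\n"
        return Phylogeny.from_newick(newick)
    else:
        raise ValueError(f"unknown tree_model {tree_model!r}")
    # deterministic tip labels in left-to-right traversal order
    counter = 0
    for nd in _walk(root):
        if not nd.children:
            counter += 1
            nd.label = f"s{counter}"
    inner = ",".join(_newick_of(ch, present) for ch in root.children)
    newick = f"({inner});\n"
    return Phylogeny.from_newick(newick)


def _walk(node: _Node):
    stack = [node]
    while stack:
        nd = stack.pop()
        yield nd
        stack.extend(reversed(nd.children))


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def _joint_covariance(
    C: np.ndarray, R: np.ndarray, lam: float | np.ndarray
) -> np.ndarray:
    """Joint covariance of vec(X) (row-major: species-by-trait) under
    lambda-rescaled Brownian motion with cross-trait covariance R."""
    lam_vec = np.atleast_1d(np.asarray(lam, float))
    p = R.shape[0]
    if lam_vec.size == 1:
        return np.kron(lambda_transform(C, float(lam_vec[0])), R)
    if lam_vec.size != p:
        raise ValueError("lambda_true must be scalar or one value per trait")
    n = C.shape[0]
    joint = np.empty((n * p, n * p))
    dC = np.diag(C)
    for s in range(p):
        for t_ in range(p):
            scale = np.sqrt(lam_vec[s] * lam_vec[t_])
            block = scale * C
            idx = np.arange(n)
            block[idx, idx] = dC
            joint[s::p, t_::p] = R[s, t_] * block
    _check_psd(joint, "per-trait-lambda joint covariance")
    return joint


def simulate_traits(
    tree: Phylogeny,
    trait_covariance: np.ndarray,
    lambda_true: float | np.ndarray,
    root_means: Sequence[float],
    seed: int = 0,
    trait_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Draw correlated traits on a tree under Brownian motion with signal lambda.

    Tip values are one draw from MVN(1 (x) root_means, C_lambda (x) R): the
    among-species covariance is the lambda-transformed tree covariance,
    Kronecker-combined with the cross-trait covariance ``R`` (Brownian rate
    units per unit branch length).
    """
    R = np.asarray(trait_covariance, float)
    root_means = np.asarray(root_means, float)
    if R.shape[0] != root_means.shape[0]:
        raise ValueError("trait dimension of covariance must match root_means")
    _check_psd(R, "trait_covariance")
    labels = tree.tip_labels
    n, p = len(labels), R.shape[0]
    if trait_names is None:
        trait_names = [f"trait{j}" for j in range(p)]
    C = tree.vcv(labels)
    joint = _joint_covariance(C, R, lambda_true)
    rng = np.random.default_rng(seed)
    if np.allclose(joint, 0.0):
        X = np.tile(root_means, (n, 1))
    else:
        w, V = np.linalg.eigh(joint)
        w = np.clip(w, 0.0, None)
        z = rng.standard_normal(n * p)
        x = np.tile(root_means, n) + V @ (np.sqrt(w) * z)
        X = x.reshape(n, p)
    return pd.DataFrame(X, index=pd.Index(labels, name="species"), columns=list(trait_names))


# ---------------------------------------------------------------------------
# per-sex success summaries
# ---------------------------------------------------------------------------

def simulate_sex_groups(
    tree: Phylogeny,
    effect_care_on_selection: float = -1.0,
    seed: int = 0,
    *,
    p_care: float = 37.0 / 64.0,
    noise_sd: float = 0.3,
    noise_lambda: float = 0.5,
    base_cv: float = 0.6,
    mean_rs: float = 4.0,
    mean_ms: float = 2.0,
    n_range: tuple[int, int] = (20, 50),
    bss_base: float = 1.0,
    bss_sd: float = 0.5,
) -> pd.DataFrame:
    """Per-species, per-sex (mean, SD, n) summaries of reproductive success,
    mating success, and the Bateman gradient, with a built-in care effect.

    A latent male-care fraction (Beta(2, 2)) drives the sex difference in
    selection: the target lnCVR of each success measure is
    ``effect * (care_frac - 0.5)`` plus phylogenetically correlated noise
    (Brownian with signal ``noise_lambda``, marginal SD ``noise_sd``), and
    male/female coefficients of variation are constructed to realise it
    exactly.  The Bateman-gradient difference is built the same way on the
    Hedges'-d scale.  A Bernoulli(``p_care``) flag marks species exhibiting
    any care; ``percent_male_care`` is reported only for those.
    """
    if not np.isfinite(effect_care_on_selection):
        raise ValueError("effect_care_on_selection must be finite")
    labels = tree.tip_labels
    n = len(labels)
    ss = np.random.SeedSequence(seed)
    s_local, s_noise = ss.spawn(2)
    rng = np.random.default_rng(s_local)

    care_frac = rng.beta(2.0, 2.0, size=n)
    has_care = rng.random(n) < p_care
    centered = care_frac - 0.5

    if noise_sd > 0:
        depth = tree.max_depth()
        rate = noise_sd**2 / depth
        noise = simulate_traits(
            tree,
            np.diag([rate, rate, rate]),
            noise_lambda,
            [0.0, 0.0, 0.0],
            seed=int(s_noise.generate_state(1)[0] % (2**31)),
            trait_names=["e_I", "e_Is", "e_B"],
        ).to_numpy()
    else:
        noise = np.zeros((n, 3))

    target_dI = effect_care_on_selection * centered + noise[:, 0]
    target_dIs = effect_care_on_selection * centered + noise[:, 1]
    target_dB = effect_care_on_selection * centered + noise[:, 2]

    rows = []
    for i, sp in enumerate(labels):
        n_m = int(rng.integers(n_range[0], n_range[1] + 1))
        n_f = int(rng.integers(n_range[0], n_range[1] + 1))
        rec: dict[str, object] = {"species": sp}
        for meas, base_mean, target in (
            ("rs", mean_rs, target_dI[i]),
            ("ms", mean_ms, target_dIs[i]),
        ):
            mean_f = base_mean * float(np.exp(rng.normal(0.0, 0.2)))
            mean_m = base_mean * float(np.exp(rng.normal(0.0, 0.2)))
            cv_f = base_cv
            cv_m = base_cv * float(np.exp(target))
            rec.update(
                {
                    f"{meas}_mean_m": mean_m,
                    f"{meas}_sd_m": cv_m * mean_m,
                    f"{meas}_n_m": n_m,
                    f"{meas}_mean_f": mean_f,
                    f"{meas}_sd_f": cv_f * mean_f,
                    f"{meas}_n_f": n_f,
                }
            )
        # Bateman gradient summaries: equal SDs, mean gap set on the d scale
        # (the small-sample factor J is an estimator detail, not simulated).
        rec.update(
            {
                "bss_mean_m": bss_base + target_dB[i] * bss_sd,
                "bss_sd_m": bss_sd,
                "bss_n_m": n_m,
                "bss_mean_f": bss_base,
                "bss_sd_f": bss_sd,
                "bss_n_f": n_f,
            }
        )
        rec["care_frac"] = care_frac[i]
        rec["has_care"] = bool(has_care[i])
        rec["percent_male_care"] = 100.0 * care_frac[i] if has_care[i] else np.nan
        rows.append(rec)
    return pd.DataFrame(rows).set_index("species")


# ---------------------------------------------------------------------------
# missingness
# ---------------------------------------------------------------------------

@dataclass
class MaskedTable:
    """A trait table with MCAR missingness plus its hidden ground truth."""

    data: pd.DataFrame   # observed table, masked cells NaN
    mask: pd.DataFrame   # boolean, True where masked
    truth: pd.DataFrame  # original complete values


def apply_missingness(
    table: pd.DataFrame,
    missing_rates: Mapping[str, float],
    seed: int = 0,
) -> MaskedTable:
    """Mask round(rate * n) cells per column, completely at random.

    The care columns are never masked.  The original values are kept in the
    returned ``truth`` frame so recovery tests can score imputations.
    """
    n = len(table)
    data = table.copy()
    mask = pd.DataFrame(False, index=table.index, columns=table.columns)
    rng = np.random.default_rng(seed)
    for col, rate in missing_rates.items():
        if not (0.0 <= rate < 1.0):
            raise ValueError(f"missing rate for {col!r} must be in [0, 1)")
        if col in PROTECTED_COLUMNS:
            raise ValueError(f"column {col!r} may not be masked")
        if col not in table.columns:
            raise KeyError(f"column {col!r} not in table")
        k = int(np.floor(rate * n + 0.5))
        if k == 0:
            continue
        rows = rng.choice(n, size=k, replace=False)
        data.iloc[rows, data.columns.get_loc(col)] = np.nan
        mask.iloc[rows, mask.columns.get_loc(col)] = True
    return MaskedTable(data=data, mask=mask, truth=table.copy())


# ---------------------------------------------------------------------------
# whole datasets
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    """Everything the pipeline needs, plus the generating ground truth."""

    tree: Phylogeny
    table: pd.DataFrame        # raw table with missingness applied
    truth: pd.DataFrame        # complete raw table
    mask: pd.DataFrame
    config: SimulationConfig

    def write(self, outdir: str) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        self.tree.write_newick(os.path.join(outdir, "tree.nwk"))
        self.table.to_csv(os.path.join(outdir, "traits.csv"))
        self.truth.to_csv(os.path.join(outdir, "traits_truth.csv"))
        self.mask.to_csv(os.path.join(outdir, "mask.csv"))
        self.config.to_yaml(os.path.join(outdir, "config.yaml"))


def simulate_dataset(config: SimulationConfig | None = None, **kwargs) -> SimulatedDataset:
    """Generate a complete comparative dataset under ``config``.

    Steps: simulate the tree; draw the six log-scale life-history traits
    (masses, gamete sizes, testis mass, clutch size) under Brownian+lambda;
    draw per-sex success summaries with the configured care-to-selection
    effect and convert them to the three selection effect sizes; assemble
    the raw species table; apply MCAR missingness at the configured
    per-column rates (care never masked).  Optionally append auxiliary
    species observed for only a subset of columns, which sharpen the
    imputation model exactly as extra literature species would.
    """
    if config is None:
        config = SimulationConfig(**kwargs)
    elif kwargs:
        raise TypeError("pass either a config or keyword overrides, not both")
    ss = np.random.SeedSequence(config.seed)
    s_tree, s_traits, s_groups, s_mask = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)
    )
    n_total = config.n_species + config.n_auxiliary
    tree = simulate_tree(n_total, config.tree_model, config.birth_rate, seed=s_tree)
    log_traits = simulate_traits(
        tree,
        config.trait_covariance,
        config.lambda_true,
        config.root_means,
        seed=s_traits,
        trait_names=[f"ln_{c}" for c in _LOG_TRAITS],
    )
    groups = simulate_sex_groups(
        tree,
        config.effect_care_on_selection,
        seed=s_groups,
        p_care=config.p_care,
        noise_sd=config.selection_noise_sd,
    )

    table = pd.DataFrame(index=log_traits.index)
    for col in _LOG_TRAITS:
        table[col] = np.exp(log_traits[f"ln_{col}"])
    # Pre-computed selection effect sizes, as a literature compilation
    # would supply them (the success summaries are the generating detail).
    table["delta_I"] = [
        ln_cvr(r.rs_mean_m, r.rs_sd_m, r.rs_n_m, r.rs_mean_f, r.rs_sd_f, r.rs_n_f)
        for r in groups.itertuples()
    ]
    table["delta_I_s"] = [
        ln_cvr(r.ms_mean_m, r.ms_sd_m, r.ms_n_m, r.ms_mean_f, r.ms_sd_f, r.ms_n_f)
        for r in groups.itertuples()
    ]
    table["delta_beta_ss"] = [
        hedges_d(r.bss_mean_m, r.bss_sd_m, r.bss_n_m, r.bss_mean_f, r.bss_sd_f, r.bss_n_f)
        for r in groups.itertuples()
    ]
    table["percent_male_care"] = groups["percent_male_care"]
    table["has_care"] = groups["has_care"]

    aux_flag = np.zeros(n_total, dtype=bool)
    if config.n_auxiliary > 0:
        aux_flag[config.n_species:] = True
        aux_rows = table.index[aux_flag]
        hide = [c for c in table.columns
                if c not in config.aux_observed_cols
                and c not in ("percent_male_care", "has_care")]
        table.loc[aux_rows, hide] = np.nan
        table.loc[aux_rows, ["percent_male_care"]] = np.nan
        table.loc[aux_rows, "has_care"] = False
    table["is_auxiliary"] = aux_flag

    truth = table.copy()
    core = table.loc[~aux_flag]
    masked_core = apply_missingness(core, config.missing_rates, seed=s_mask)
    out = table.copy()
    out.loc[~aux_flag, :] = masked_core.data
    mask = pd.DataFrame(False, index=table.index, columns=table.columns)
    mask.loc[~aux_flag, :] = masked_core.mask
    return SimulatedDataset(tree=tree, table=out, truth=truth, mask=mask, config=config)
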