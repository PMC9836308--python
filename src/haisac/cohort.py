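"""Seeded synthetic cohorts with the three-group CU / MCI / DAT structure.

Two fidelity levels are provided.  The *scale-level* generator draws every
scale score from a group-conditional normal calibrated to the published group
means and SDs, either untruncated (``mode="untruncated"``, the right choice
for ROC calibration work where the binormal model is the reference) or
clipped-and-snapped to each instrument's score grid (``mode="bounded"``).
The *item-level* generator realizes a two-factor latent structure over the
five HAI-SAC items (objective semantic-memory/contextual-binding factor plus
an informant factor) and discretizes into raw item responses, so that the
scoring engine and the factor-analysis layer can be exercised end to end.

Diagnosis labels are generative: group membership determines the score
distribution, never the other way around.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .scoring import ITEM_CSV_COLUMNS

__all__ = [
    "GroupParams",
    "CohortConfig",
    "LatentFactorSpec",
    "load_config",
    "default_config",
    "default_factor_spec",
    "simulate_scale_cohort",
    "simulate_item_cohort",
    "moment_check",
    "SCALE_VARIABLES",
]

GROUP_ORDER = ("CU", "MCI", "DAT")

SCALE_VARIABLES = (
    "age", "education_years", "cdr_sb", "npi_sb", "iadl",
    "casi", "mmse", "moca",
    "haisac_total", "haisac3", "cnocd", "ml", "rfo", "haisaci", "cd", "fd",
)

#: Variables where larger values mean *worse* status; the shared within-group
#: latent factor enters these with a negative sign so that a positive
#: ``within_group_correlation`` induces the empirically observed sign pattern
#: (cognitive tests positively inter-correlated, negatively with CDR-SB/NPI-SB).
_NEGATIVE_SENSE = frozenset({"age", "cdr_sb", "npi_sb"})


@dataclass(frozen=True)
class GroupParams:
    """Sample size, sex mix and per-variable normal moments for one group."""

    label: str
    n: int
    male_proportion: float
    means: Mapping[str, float]
    sds: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError(f"group {self.label}: n must be positive, got {self.n}")
        if not 0.0 <= self.male_proportion <= 1.0:
            raise ValueError(f"group {self.label}: male_proportion outside [0, 1]")
        for v, sd in self.sds.items():
            if sd < 0:
                raise ValueError(f"group {self.label}: SD of {v} is negative")


@dataclass(frozen=True)
class CohortConfig:
    """Full simulator configuration: three groups plus generation options."""

    groups: tuple[GroupParams, ...]
    seed: int | None = None
    mode: str = "untruncated"
    within_group_correlation: float = 0.0
    bounds: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("untruncated", "bounded"):
            raise ValueError(f"mode must be 'untruncated' or 'bounded', got {self.mode!r}")
        if not 0.0 <= self.within_group_correlation < 1.0:
            raise ValueError("within_group_correlation must lie in [0, 1)")

    def group(self, label: str) -> GroupParams:
        for g in self.groups:
            if g.label == label:
                return g
        raise KeyError(label)


@dataclass(frozen=True)
class LatentFactorSpec:
    """Two-factor model over the five HAI-SAC items.

    ``loadings`` is items × factors in the order ``items``; uniquenesses are
    ``1 − λᵢᵀ Φ λᵢ`` for each standardized item.  ``cd_prob`` / ``fd_prob``
    give per-group Bernoulli probabilities for the binary informant items.
    """

    items: tuple[str, ...]
    factor_names: tuple[str, ...]
    loadings: np.ndarray
    factor_correlation: float
    cd_prob: Mapping[str, float]
    fd_prob: Mapping[str, float]

    def __post_init__(self) -> None:
        L = np.asarray(self.loadings, dtype=float)
        object.__setattr__(self, "loadings", L)
        if L.shape != (len(self.items), len(self.factor_names)):
            raise ValueError("loadings shape does not match items × factors")
        if np.any(np.abs(L) > 1):
            raise ValueError("standardized loadings must have |loading| <= 1")
        if np.any(self.uniquenesses < 0):
            raise ValueError(
                "implied communality exceeds 1 for some item; "
                "the loading/correlation configuration is not positive definite"
            )

    @property
    def phi(self) -> np.ndarray:
        """Factor correlation matrix."""
        k = len(self.factor_names)
        phi = np.full((k, k), self.factor_correlation, dtype=float)
        np.fill_diagonal(phi, 1.0)
        return phi

    @property
    def communalities(self) -> np.ndarray:
        return np.einsum("ij,jk,ik->i", self.loadings, self.phi, self.loadings)

    @property
    def uniquenesses(self) -> np.ndarray:
        return 1.0 - self.communalities

    def implied_correlation(self) -> np.ndarray:
        """Model-implied item correlation matrix ΛΦΛᵀ + Ψ.

        Singular but positive semi-definite configurations (e.g. a rank-1
        model with zero uniquenesses) are legal; only an indefinite implied
        covariance is a configuration error.
        """
        R = self.loadings @ self.phi @ self.loadings.T + np.diag(self.uniquenesses)
        if np.min(np.linalg.eigvalsh(R)) < -1e-8:
            raise ValueError("implied item correlation matrix is not positive semi-definite")
        return R


# ---------------------------------------------------------------------------
# Configuration loading

def _read_yaml(path=None) -> dict:
    if path is None:
        text = resources.files("haisac.data").joinpath("reference_cohort.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return yaml.safe_load(text)


def load_config(
    path=None,
    *,
    seed: int | None = None,
    mode: str = "untruncated",
    within_group_correlation: float = 0.0,
) -> CohortConfig:
    """Load a :class:`CohortConfig` from YAML (packaged defaults when ``path`` is None)."""
    raw = _read_yaml(path)
    try:
        groups = []
        for label in GROUP_ORDER:
            g = raw["groups"][label]
            variables = g["variables"]
            groups.append(
                GroupParams(
                    label=label,
                    n=int(g["n"]),
                    male_proportion=float(g["male_proportion"]),
                    means={v: float(spec["mean"]) for v, spec in variables.items()},
                    sds={v: float(spec["sd"]) for v, spec in variables.items()},
                )
            )
        bounds = {v: (float(lo), float(hi)) for v, (lo, hi) in raw.get("bounds", {}).items()}
    except (KeyError, TypeError) as exc:
        raise ValueError(f"malformed cohort config: missing or invalid field {exc}") from exc
    return CohortConfig(
        groups=tuple(groups),
        seed=seed,
        mode=mode,
        within_group_correlation=within_group_correlation,
        bounds=bounds,
    )


def default_config(**kwargs) -> CohortConfig:
    """Packaged default configuration (published group moments)."""
    return load_config(None, **kwargs)


def default_factor_spec(path=None) -> LatentFactorSpec:
    """Packaged default two-factor model (published loadings, φ = 0.30)."""
    raw = _read_yaml(path)
    try:
        fm = raw["factor_model"]
        items = tuple(fm["items"])
        loadings = np.array([fm["loadings"][it] for it in items], dtype=float)
        return LatentFactorSpec(
            items=items,
            factor_names=tuple(fm["factors"]),
            loadings=loadings,
            factor_correlation=float(fm["factor_correlation"]),
            cd_prob={k: float(v) for k, v in fm["cd_no_decline_prob"].items()},
            fd_prob={k: float(v) for k, v in fm["fd_no_interference_prob"].items()},
        )
    except (KeyError, TypeError) as exc:
        raise ValueError(f"malformed factor_model config: missing field {exc}") from exc


# ---------------------------------------------------------------------------
# Scale-level generation

def _snap_to_grid(values: np.ndarray, variable: str) -> np.ndarray:
    """Snap to the instrument's score grid: CD ∈ {0,8}, FD ∈ {0,12}, ML even,
    CDR-SB half points, integers elsewhere."""
    if variable == "cd":
        return np.where(values >= 4, 8.0, 0.0)
    if variable == "fd":
        return np.where(values >= 6, 12.0, 0.0)
    if variable == "ml":
        return 2.0 * np.round(values / 2.0)
    if variable == "cdr_sb":
        return np.round(values * 2.0) / 2.0
    return np.round(values)


def _resolve_rng(config: CohortConfig, seed: int | None):
    """Seed resolution: explicit argument wins, then the config's seed, then
    fresh OS entropy (recorded so the draw stays auditable)."""
    if seed is None:
        seed = config.seed
    if seed is None:
        seed = int(np.random.SeedSequence().entropy % (2**31))
    return np.random.default_rng(seed), seed


def simulate_scale_cohort(config: CohortConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw a scale-level cohort: one row per subject, group-conditional normals.

    In ``untruncated`` mode each variable keeps its exact normal draw; in
    ``bounded`` mode draws are clipped to the configured bounds and snapped to
    the instrument score grids.  Variables are independent within group unless
    ``within_group_correlation`` mixes in a shared per-subject latent effect.
    The returned frame carries the realized seed in ``attrs['seed']``.
    """
    rng, used_seed = _resolve_rng(config, seed)
    rho = config.within_group_correlation
    frames = []
    offset = 0
    for g in config.groups:
        cols: dict[str, np.ndarray] = {}
        shared = rng.standard_normal(g.n)
        for v in SCALE_VARIABLES:
            if v not in g.means:
                continue
            z = rng.standard_normal(g.n)
            if rho > 0.0:
                sign = -1.0 if v in _NEGATIVE_SENSE else 1.0
                z = sign * np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * z
            if config.mode == "bounded" and v in ("cd", "fd"):
                # two-point items: maximum × Bernoulli(mean/maximum), realized
                # through the latent normal so the copula structure survives
                hi = config.bounds.get(v, (0.0, {"cd": 8.0, "fd": 12.0}[v]))[1]
                p = float(np.clip(g.means[v] / hi, 0.0, 1.0))
                x = hi * (stats.norm.cdf(z) < p).astype(float)
            else:
                x = g.means[v] + g.sds[v] * z
                if config.mode == "bounded":
                    lo, hi = config.bounds.get(v, (0.0, np.inf))
                    x = _snap_to_grid(np.clip(x, lo, hi), v)
            cols[v] = x
        df = pd.DataFrame(cols)
        df.insert(0, "sex", np.where(rng.random(g.n) < g.male_proportion, "M", "F"))
        df.insert(0, "group", g.label)
        df.insert(0, "subject_id", [f"S{offset + i + 1:04d}" for i in range(g.n)])
        offset += g.n
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.attrs["seed"] = used_seed
    out.attrs["mode"] = config.mode
    return out


# ---------------------------------------------------------------------------
# Item-level generation

def _decompose_cnocd(total: int) -> tuple[int, int, str]:
    """Deterministically split a CNOCD total into naming / color / watch parts.

    The watch detail (4 points) is only awarded on totals ≥ 13, which keeps
    the decomposition single-valued; re-scoring the parts reproduces the total
    exactly for every value in [0, 16].
    """
    watch = 4 if total >= 13 else 0
    rest = total - watch
    naming = min(6, rest)
    color = rest - naming
    return naming, color, ("full" if watch else "none")


def simulate_item_cohort(
    config: CohortConfig,
    spec: LatentFactorSpec | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw an item-level cohort realizing the two-factor latent structure.

    Per subject, two correlated standard-normal factors are drawn; each
    standardized item is ``λᵢᵀ f + √ψᵢ εᵢ``.  Objective items are shifted and
    scaled to the group's published item moments and discretized onto the raw
    response grids (naming/color counts, placement count, function count);
    the binary informant items are produced by thresholding their latent at
    the group's Bernoulli probability, so the latent correlation structure
    survives as a threshold (probit) model.  Columns follow the item CSV
    schema plus a leading ``group`` column.
    """
    if spec is None:
        spec = default_factor_spec()
    spec.implied_correlation()  # raises if the configuration is degenerate
    rng, used_seed = _resolve_rng(config, seed)
    chol = np.linalg.cholesky(spec.phi)
    sqrt_psi = np.sqrt(spec.uniquenesses)
    idx = {item: i for i, item in enumerate(spec.items)}
    rows: list[dict] = []
    offset = 0
    for g in config.groups:
        factors = rng.standard_normal((g.n, len(spec.factor_names))) @ chol.T
        eps = rng.standard_normal((g.n, len(spec.items)))
        z = factors @ spec.loadings.T + eps * sqrt_psi
        cnocd = np.clip(np.round(g.means["cnocd"] + g.sds["cnocd"] * z[:, idx["cnocd"]]), 0, 16).astype(int)
        rfo = np.clip(np.round(g.means["rfo"] + g.sds["rfo"] * z[:, idx["rfo"]]), 0, 12).astype(int)
        ml_score = g.means["ml"] + g.sds["ml"] * z[:, idx["ml"]]
        ml_count = np.clip(np.round(ml_score / 2.0), 0, 6).astype(int)
        cd_flag = z[:, idx["cd"]] > stats.norm.ppf(1.0 - spec.cd_prob[g.label])
        fd_flag = z[:, idx["fd"]] > stats.norm.ppf(1.0 - spec.fd_prob[g.label])
        for i in range(g.n):
            naming, color, watch = _decompose_cnocd(int(cnocd[i]))
            row = {"group": g.label, "subject_id": f"S{offset + i + 1:04d}"}
            for j in range(1, 7):
                row[f"name_{j}"] = j <= naming
                row[f"color_{j}"] = j <= color
            row["watch_grade"] = watch
            row["ml_correct"] = int(ml_count[i])
            row["rfo_correct"] = int(rfo[i])
            row["cd_no_decline"] = bool(cd_flag[i])
            row["fd_no_interference"] = bool(fd_flag[i])
            rows.append(row)
        offset += g.n
    out = pd.DataFrame(rows, columns=["group"] + ITEM_CSV_COLUMNS)
    out.attrs["seed"] = used_seed
    return out


# ---------------------------------------------------------------------------
# Moment diagnostics

def moment_check(cohort: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Compare per-group sample moments against the configured targets.

    Returns one row per (group, variable) with target/sample mean and SD and
    a ``flagged`` column marking deviations beyond four standard errors
    (SE(mean) = σ/√n, SE(sd) ≈ σ/√(2(n−1))).  Intended for untruncated
    cohorts, where the targets are exact.
    """
    if cohort.empty:
        raise ValueError("cohort is empty")
    records = []
    for g in config.groups:
        sub = cohort[cohort["group"] == g.label]
        if sub.empty:
            raise ValueError(f"cohort contains no subjects for group {g.label}")
        n = len(sub)
        for v in g.means:
            if v not in cohort.columns:
                raise ValueError(f"cohort lacks configured variable {v!r}")
            m, s = float(sub[v].mean()), float(sub[v].std(ddof=1))
            se_mean = g.sds[v] / np.sqrt(n)
            se_sd = g.sds[v] / np.sqrt(2.0 * max(n - 1, 1))
            flagged = bool(
                (se_mean > 0 and abs(m - g.means[v]) > 4.0 * se_mean)
                or (se_sd > 0 and abs(s - g.sds[v]) > 4.0 * se_sd)
                or (g.sds[v] == 0 and (m != g.means[v] or s != 0))
            )
            records.append(
                {
                    "group": g.label,
                    "variable": v,
                    "target_mean": g.means[v],
                    "sample_mean": m,
                    "target_sd": g.sds[v],
                    "sample_sd": s,
                    "flagged": flagged,
                }
            )
    return pd.DataFrame(records)
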