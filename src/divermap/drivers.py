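"""Inference on what drives plant-fungal richness correlations.

Three lines of evidence, mirroring the symbiosis / environment / legacy
hypotheses:

* a global additive smooth model of fungal richness on plant richness plus
  environmental covariates, with the partial percent deviance uniquely
  attributable to plant richness (nested-model deviance partition);
* an ecoregion-level smooth model of the correlation itself on host-plant
  biomass, climate stability and human development (plus covariate means);
* a sign-concordance chi-squared test: within each ecoregion, paired linear
  models give the sign of the plant and fungal responses to an
  environmental gradient, and the 2x2 cross-tabulation of sign agreement
  against correlation sign is tested for independence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .correlation import CellSample, ScanResult, spearman_correlation
from .smooth import AdditiveModel, CollinearityError

GLOBAL_COVARIATES = ("temperature", "precipitation", "ph", "soc",
                     "nitrogen", "phosphorus", "elevation")
DRIVER_COVARIATES = GLOBAL_COVARIATES + ("raw_fungal", "raw_plant")


# ---------------------------------------------------------------------------
# deviance partitioning (symbiosis evidence)

@dataclass
class DeviancePartition:
    deviance_full: float
    deviance_reduced: float
    deviance_null: float
    partial_pct: float


@dataclass
class GlobalDriverFit:
    pair: str
    model: AdditiveModel
    partition: DeviancePartition
    deviance_explained_pct: float
    n: int


def partial_deviance_explained(full: float, reduced: float, null: float) -> float:
    """Percent of null deviance uniquely explained by the dropped predictor:
    ``100 * (dev(reduced) - dev(full)) / dev(null)``.

    A reduced deviance below the full one violates nesting; it is clipped to
    zero with a warning rather than returned negative.
    """
    if null <= 0:
        raise ZeroDivisionError("null deviance must be positive")
    diff = reduced - full
    if diff < 0:
        warnings.warn("reduced model outperforms full model (non-nested "
                      "deviances); partial deviance clipped to 0")
        diff = 0.0
    return float(np.clip(100.0 * diff / null, 0.0, 100.0))


def fit_global_driver_model(sample: CellSample,
                            covariates: Sequence[str] = GLOBAL_COVARIATES,
                            k: int = 3, alpha: float = 0.0,
                            pair: str = "") -> GlobalDriverFit:
    """Fungal richness ~ s(plant) + s(covariates); partial deviance of plant.

    The reduced model drops the plant term; the partition is on the
    intercept-only (null) deviance.
    """
    tbl = sample.table
    missing = [c for c in covariates if c not in tbl.columns]
    if missing:
        raise ValueError(f"covariates missing from sample: {missing}")
    y = tbl["fungal"].to_numpy()
    terms = {"plant": tbl["plant"].to_numpy()}
    for c in covariates:
        terms[c] = tbl[c].to_numpy()
    full = AdditiveModel(y, terms, k=k, alpha=alpha)
    reduced = full.refit_without("plant")
    partial = partial_deviance_explained(full.deviance, reduced.deviance,
                                         full.null_deviance)
    partition = DeviancePartition(full.deviance, reduced.deviance,
                                  full.null_deviance, partial)
    return GlobalDriverFit(pair, full, partition,
                           full.deviance_explained_pct, sample.achieved_n)


# ---------------------------------------------------------------------------
# correlation-driver smooth model (symbiosis/legacy evidence)

@dataclass
class CorrelationDriverFit:
    model: AdditiveModel
    deviance_explained_pct: float
    n_zones: int

    def partial_residuals(self, term: str):
        return self.model.partial_residuals(term)

    def partial_slope(self, term: str):
        return self.model.partial_slope(term)

    def term_partial_deviance(self, term: str) -> float:
        reduced = self.model.refit_without(term)
        return partial_deviance_explained(self.model.deviance, reduced.deviance,
                                          self.model.null_deviance)


def build_zone_driver_table(scan: ScanResult, pair: str,
                            host_col: str) -> pd.DataFrame:
    """Per-ecoregion table of rho plus covariate means of the *same* sampled
    cells used for the correlations."""
    eco = scan.records[(scan.records["scale"] == "ecoregion")
                       & (scan.records["pair"] == pair)]
    rows = []
    for _, rec in eco.iterrows():
        sample = scan.sample(pair, "ecoregion", int(rec["zone_id"]))
        row = {"zone_id": int(rec["zone_id"]), "rho": rec["rho"], "n": rec["n"]}
        for col in sample.table.columns:
            if col in ("row", "col", "zone_id", "plant", "fungal"):
                continue
            row[col] = float(sample.table[col].mean())
        if host_col in sample.table.columns:
            row["host_pct"] = float(sample.table[host_col].mean())
        rows.append(row)
    return pd.DataFrame(rows).dropna(subset=["rho"])


def fit_correlation_driver_model(zone_table: pd.DataFrame,
                                 drivers: Sequence[str] = (
                                     "host_pct", "climate_stability", "human_development"),
                                 covariates: Sequence[str] = DRIVER_COVARIATES,
                                 k: int = 4, alpha: float = 1.0,
                                 min_zones: int = 50) -> CorrelationDriverFit:
    """Smooth model of ecoregion-level rho on its hypothesized drivers.

    ``zone_table`` must carry a ``rho`` column and one column per driver and
    covariate (zone means).  k=4 basis functions per term; a mild default
    penalty keeps the near-saturated ecoregion-level fit stable.
    """
    cols = list(drivers) + [c for c in covariates if c in zone_table.columns]
    tbl = zone_table.dropna(subset=["rho"] + [c for c in cols if c in zone_table.columns])
    if len(tbl) < min_zones:
        raise ValueError(f"need at least {min_zones} ecoregions, have {len(tbl)}")
    missing = [c for c in drivers if c not in tbl.columns]
    if missing:
        raise ValueError(f"driver columns missing: {missing}")
    terms = {c: tbl[c].to_numpy() for c in cols}
    model = AdditiveModel(tbl["rho"].to_numpy(), terms, k=k, alpha=alpha)
    return CorrelationDriverFit(model, model.deviance_explained_pct, len(tbl))


# ---------------------------------------------------------------------------
# sign-concordance procedure (environment evidence)

@dataclass
class SignPair:
    zone_id: int
    env_var: str
    plant_coef: float
    plant_p: float
    fungal_coef: float
    fungal_p: float
    rho: float
    n: int

    @property
    def rho_sign(self) -> int:
        return int(np.sign(self.rho))

    @property
    def signs_agree(self) -> bool:
        return np.sign(self.plant_coef) == np.sign(self.fungal_coef)


class DegenerateScalingError(ValueError):
    """A variable is constant within the zone; min-max scaling undefined."""


def _minmax(x: np.ndarray, name: str) -> np.ndarray:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        raise DegenerateScalingError(f"variable {name!r} is constant in this zone")
    return (x - lo) / (hi - lo)


def fit_zone_sign_models(sample: CellSample, env_var: str, host_col: str,
                         min_unique: int = 10) -> SignPair:
    """Paired linear models extracting the signed response of each taxon to
    one environmental gradient within one ecoregion.

    plant ~ env + fungal + host ; fungal ~ env + plant + host.  All
    variables are min-max scaled to [0, 1] within the zone first; the
    opposite taxon's richness and host-plant biomass are covariates to
    strip host-symbiont coupling variation.
    """
    tbl = sample.table
    env = tbl[env_var].to_numpy(dtype=float)
    if np.unique(env).size < min_unique:
        raise ValueError(f"{env_var!r} has fewer than {min_unique} unique values")
    plant = _minmax(tbl["plant"].to_numpy(dtype=float), "plant")
    fungal = _minmax(tbl["fungal"].to_numpy(dtype=float), "fungal")
    env_s = _minmax(env, env_var)
    host = _minmax(tbl[host_col].to_numpy(dtype=float), host_col)

    def _env_coef(y, others):
        x = sm.add_constant(np.column_stack([env_s] + others))
        fit = sm.OLS(y, x).fit()
        return float(fit.params[1]), float(fit.pvalues[1])

    plant_coef, plant_p = _env_coef(plant, [fungal, host])
    fungal_coef, fungal_p = _env_coef(fungal, [plant, host])
    rho = spearman_correlation(sample).rho
    return SignPair(sample.zone_id, env_var, plant_coef, plant_p,
                    fungal_coef, fungal_p, rho, sample.achieved_n)


def collect_sign_pairs(scan: ScanResult, pair: str, env_var: str, host_col: str,
                       min_unique: int = 10) -> tuple[list[SignPair], pd.DataFrame]:
    """Sign models for every usable ecoregion; unusable zones are reported."""
    pairs_out: list[SignPair] = []
    dropped = []
    for (p, scale, zone_id), sample in sorted(scan.samples.items()):
        if p != pair or scale != "ecoregion":
            continue
        try:
            pairs_out.append(fit_zone_sign_models(sample, env_var, host_col,
                                                  min_unique=min_unique))
        except (ValueError, DegenerateScalingError) as exc:
            dropped.append({"zone_id": zone_id, "reason": str(exc)})
    return pairs_out, pd.DataFrame(dropped, columns=["zone_id", "reason"])


@dataclass
class ConcordanceResult:
    """2x2 sign-agreement x correlation-sign table and its chi-squared test.

    ``table`` rows are (signs agree, signs disagree); columns are
    (rho positive, rho negative).  The uncorrected Pearson chi-squared is
    primary; the Yates-corrected version is carried as a diagnostic.
    """

    table: np.ndarray
    chi2: float
    p: float
    chi2_corrected: float
    p_corrected: float
    n_used: int
    n_excluded: int
    low_expected: bool


def sign_concordance_test(pairs: Sequence[SignPair], alpha: float = 0.05,
                          ) -> ConcordanceResult:
    """Chi-squared test of sign agreement vs correlation sign.

    Only zones where both coefficients have p < ``alpha`` (and rho is
    nonzero and finite) enter the table; the filter removes zones, never
    flips recorded signs.
    """
    used = [sp for sp in pairs
            if sp.plant_p < alpha and sp.fungal_p < alpha
            and np.isfinite(sp.rho) and sp.rho != 0
            and sp.plant_coef != 0 and sp.fungal_coef != 0]
    n_excluded = len(pairs) - len(used)
    table = np.zeros((2, 2), dtype=int)
    for sp in used:
        i = 0 if sp.signs_agree else 1
        j = 0 if sp.rho > 0 else 1
        table[i, j] += 1
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate 2x2 table after the p-filter "
                         f"(counts {table.tolist()})")
    chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
    chi2_c, p_c, _, _ = stats.chi2_contingency(table, correction=True)
    return ConcordanceResult(table, float(chi2), float(p), float(chi2_c),
                             float(p_c), len(used), n_excluded,
                             bool((expected < 5).any()))


def zone_covariate_collinearity(scan: ScanResult, pair: str,
                                columns: Sequence[str]) -> dict[int, float]:
    """Max absolute pairwise Pearson r among covariates, per ecoregion."""
    out: dict[int, float] = {}
    for (p, scale, zone_id), sample in scan.samples.items():
        if p != pair or scale != "ecoregion":
            continue
        sub = sample.table[list(columns)].to_numpy(dtype=float)
        keep = [j for j in range(sub.shape[1]) if np.std(sub[:, j]) > 0]
        if len(keep) < 2:
            out[zone_id] = 0.0
            continue
        corr = np.corrcoef(sub[:, keep], rowvar=False)
        np.fill_diagonal(corr, 0.0)
        out[zone_id] = float(np.max(np.abs(corr)))
    return out


def collinearity_sensitivity(pairs: Sequence[SignPair],
                             zone_max_abs_corr: Mapping[int, float],
                             cutoffs: Sequence[float] = (0.85, 0.80),
                             alpha: float = 0.05) -> pd.DataFrame:
    """Re-run the concordance test after dropping high-collinearity zones."""
    rows = []
    for cutoff in cutoffs:
        kept = [sp for sp in pairs
                if zone_max_abs_corr.get(sp.zone_id, 0.0) <= cutoff]
        dropped_frac = 1.0 - len(kept) / len(pairs) if pairs else np.nan
        row = {"cutoff": cutoff, "n_zones": len(kept), "dropped_fraction": dropped_frac}
        try:
            res = sign_concordance_test(kept, alpha=alpha)
            row.update(chi2=res.chi2, p=res.p, note="")
        except ValueError as exc:
            row.update(chi2=np.nan, p=np.nan, note=str(exc))
        rows.append(row)
    return pd.DataFrame(rows)


def normality_screen(scan: ScanResult, pair: str,
                     responses: Sequence[str] = ("plant", "fungal"),
                     alpha: float = 0.05, max_n: int = 5000,
                     seed: int = 0) -> pd.DataFrame:
    """Shapiro-Wilk screen of per-zone richness distributions (diagnostic).

    Flags p < alpha for human review; never blocks the pipeline.  Samples
    larger than the test's validity range are subsampled deterministically.
    """
    rows = []
    for (p, scale, zone_id), sample in sorted(scan.samples.items()):
        if p != pair or scale != "ecoregion":
            continue
        for resp in responses:
            x = sample.table[resp].to_numpy(dtype=float)
            row = {"zone_id": zone_id, "response": resp, "n": x.size}
            if np.unique(x).size < 3 or x.size < 3:
                row.update(W=np.nan, p=np.nan, flagged=False, note="not-testable")
            else:
                if x.size > max_n:
                    rng = np.random.default_rng(
                        np.random.SeedSequence(seed, spawn_key=(zone_id + 1,)))
                    x = rng.choice(x, size=max_n, replace=False)
                w, pval = stats.shapiro(x)
                row.update(W=float(w), p=float(pval), flagged=bool(pval < alpha), note="")
            rows.append(row)
    return pd.DataFrame(rows)
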