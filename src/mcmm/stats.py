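"""Measurement processing and validation/association statistics.

Covers the pipeline's statistical surface: endpoint-concentration flux
estimation, within-study Z-scoring, Pearson correlation between measured and
predicted fluxes, Mann-Whitney group comparison, and the covariate-adjusted
clinical-marker association scan with Benjamini-Yekutieli FDR control (valid
under arbitrary dependence among markers).

The association scan follows the model/results idiom:
``ClinicalAssociationModel(markers, flux, covariates).fit()`` returns a
results object with per-marker standardized coefficients, raw and
FDR-adjusted p-values, and a ``summary()`` table. Covariates are age, sex and
sequencing vendor; BMI is deliberately not a covariate because it is itself
downstream of butyrate production.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AssociationResult",
    "ClinicalAssociationModel",
    "ClinicalAssociationResults",
    "DegenerateGroupError",
    "FitError",
    "endpoint_flux",
    "zscore_within",
    "pearson_assoc",
    "group_test",
    "clinical_scan",
    "validate_study_table",
]

log = logging.getLogger(__name__)

STUDY_TABLE_COLUMNS = (
    "sample_id", "study_id", "treatment", "dilution_factor",
    "metabolite", "measured_flux", "predicted_flux",
)


class DegenerateGroupError(ValueError):
    """A Z-scoring group with fewer than two distinct values."""


class FitError(ValueError):
    """Collinear or otherwise unfittable OLS design."""


def endpoint_flux(c_start: float, c_end: float, hours: float,
                  od: float | None = None) -> float:
    """Production flux from endpoint concentrations: (c_end - c_start)/hours,
    optionally normalized to total biomass by OD600.

    Negative results mean net consumption and are returned as-is.
    """
    if hours <= 0:
        raise ValueError("culturing time must be positive")
    flux = (c_end - c_start) / hours
    if od is not None:
        if od <= 0:
            raise ValueError("OD600 must be positive")
        flux /= od
    return flux


def validate_study_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check the tidy study-table contract (columns + unique keys)."""
    missing = set(STUDY_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"study table missing columns {sorted(missing)}")
    keys = ["sample_id", "metabolite", "treatment"]
    if df.duplicated(subset=keys).any():
        raise ValueError("study table has duplicated (sample, metabolite, "
                         "treatment) keys")
    return df


def zscore_within(table: pd.DataFrame, group_key: str = "study_id",
                  columns=("measured_flux", "predicted_flux")
                  ) -> pd.DataFrame:
    """Z-score the given columns within each group (sample sd, n-1).

    After scoring, each group has mean 0 and sd 1 in every scored column.
    Groups of one sample or with a constant column are an error naming the
    group.
    """
    out = table.copy()
    for group, idx in table.groupby(group_key).groups.items():
        for col in columns:
            values = table.loc[idx, col].astype(float)
            if len(values) < 2 or values.nunique() < 2:
                raise DegenerateGroupError(
                    f"group {group!r}: column {col!r} has fewer than two "
                    "distinct values"
                )
            out.loc[idx, col] = (values - values.mean()) / values.std(ddof=1)
    return out


def pearson_assoc(x, y) -> tuple[float, float]:
    """Pearson product-moment r and two-sided p (t transform, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: zero variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def group_test(values_a, values_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact p for combined n <= 20 without ties; midrank normal approximation
    with continuity correction otherwise. Returns (U of the first group, p).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size + b.size <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


@dataclass
class AssociationResult:
    """One marker's covariate-adjusted association with the flux."""

    marker_id: str
    beta: float          # standardized flux coefficient
    p_raw: float
    p_fdr: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p_fdr < 0.05


def _zscore(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std(ddof=1)


class ClinicalAssociationModel:
    """OLS scan of clinical markers against a predicted flux.

    Each marker is regressed on the flux plus age, sex and sequencing-vendor
    covariates (marker ~ flux + age + sex + vendor), all continuous variables
    z-standardized on the marker's complete cases, and the flux coefficient
    tested by two-sided t-test. P-values are Benjamini-Yekutieli-adjusted
    across markers.
    """

    def __init__(self, markers: pd.DataFrame, flux, covariates: pd.DataFrame,
                 min_cases: int = 10):
        self.markers = markers
        self.flux = np.asarray(flux, dtype=float)
        self.covariates = covariates
        self.min_cases = min_cases
        if len(markers) != len(self.flux) or len(covariates) != len(self.flux):
            raise ValueError("markers, flux and covariates must align row-wise")
        for col in ("age", "sex", "vendor"):
            if col not in covariates.columns:
                raise ValueError(f"covariates table missing {col!r}")

    def _design(self, mask: np.ndarray) -> pd.DataFrame:
        cov = self.covariates.loc[mask]
        X = pd.DataFrame(index=cov.index)
        X["flux"] = _zscore(self.flux[mask])
        X["age"] = _zscore(cov["age"].to_numpy(dtype=float))
        X["sex"] = cov["sex"].to_numpy(dtype=float)
        vendor_dummies = pd.get_dummies(cov["vendor"], prefix="vendor",
                                        drop_first=True, dtype=float)
        X = pd.concat([X, vendor_dummies], axis=1)
        return sm.add_constant(X, has_constant="add")

    def fit(self, alpha: float = 0.05) -> "ClinicalAssociationResults":
        results: list[AssociationResult] = []
        skipped: list[str] = []
        cov_ok = self.covariates.notna().all(axis=1).to_numpy()
        flux_ok = np.isfinite(self.flux)
        for marker_id in self.markers.columns:
            y_raw = self.markers[marker_id].to_numpy(dtype=float)
            mask = cov_ok & flux_ok & np.isfinite(y_raw)
            n = int(mask.sum())
            if n < self.min_cases:
                skipped.append(marker_id)
                log.info("marker %s skipped: %d complete cases < %d",
                         marker_id, n, self.min_cases)
                continue
            X = self._design(mask)
            if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
                raise FitError(
                    f"marker {marker_id}: perfectly collinear covariates"
                )
            y = _zscore(y_raw[mask])
            ols = sm.OLS(y, X).fit()
            if ols.mse_resid < 1e-12:
                raise FitError(
                    f"marker {marker_id}: marker collinear with the design "
                    "(zero residual variance)"
                )
            results.append(AssociationResult(
                marker_id=marker_id,
                beta=float(ols.params["flux"]),
                p_raw=float(ols.pvalues["flux"]),
                p_fdr=float("nan"),
                n=n,
            ))
        if results:
            adjusted = multipletests([r.p_raw for r in results], alpha=alpha,
                                     method="fdr_by")[1]
            for r, p in zip(results, adjusted):
                r.p_fdr = float(min(1.0, p))
        return ClinicalAssociationResults(self, results, skipped, alpha)


@dataclass
class ClinicalAssociationResults:
    model: ClinicalAssociationModel
    results: list
    skipped: list
    alpha: float

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"marker": r.marker_id, "beta": r.beta, "p_raw": r.p_raw,
              "p_fdr": r.p_fdr, "n": r.n, "significant": r.significant}
             for r in self.results]
        )

    @property
    def n_significant(self) -> int:
        return sum(r.p_fdr < self.alpha for r in self.results)

    def summary(self) -> str:
        df = self.frame()
        lines = [
            "Clinical association scan (OLS, BY-FDR)",
            "=" * 56,
            f"markers tested: {len(self.results)}  skipped: {len(self.skipped)}",
            f"significant at FDR {self.alpha:g}: {self.n_significant}",
            "-" * 56,
            df.sort_values("p_fdr").head(20).to_string(index=False),
        ]
        return "\n".join(lines)


def clinical_scan(flux, markers: pd.DataFrame, covariates: pd.DataFrame,
                  alpha: float = 0.05) -> list[AssociationResult]:
    """Procedural wrapper over :class:`ClinicalAssociationModel`."""
    fitted = ClinicalAssociationModel(markers, flux, covariates).fit(alpha)
    return fitted.results
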