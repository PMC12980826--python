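"""Sign-split multiple linear regression for rAAV adsorption.

The adsorption ratio A (%) of a capsid on a solid surface is modelled as

    A = β0 + β1·θ + β2·ζpos + β3·ζneg + β4·S_hydrophobic + β5·S_hydrophilic

where θ is the surface contact angle (deg), ζpos/ζneg the sign-split
surface zeta potential (mV), and S_* the capsid outer side-chain SASA
descriptors (Å²).  Splitting ζ by sign lets electrostatic attraction to
positive surfaces and the residual (charge-patch mediated) adsorption to
negative surfaces carry separate coefficients.  Nested variants:

    S1:    {θ, ζ}
    S2:    {θ, ζpos, ζneg}
    final: {θ, ζpos, ζneg, S_hydrophobic, S_hydrophilic}

Fits are ordinary least squares; standardized coefficients come from
z-scoring all variables (including the response).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "RegressionFit",
    "split_zeta",
    "merge_conditions_descriptors",
    "build_design",
    "fit_ols",
    "standardized_fit",
    "fit_model",
    "predict",
    "validation_r2",
    "VARIANT_COLUMNS",
]

VARIANT_COLUMNS = {
    "S1": ["theta_deg", "zeta_mV"],
    "S2": ["theta_deg", "zeta_pos_mV", "zeta_neg_mV"],
    "final": [
        "theta_deg",
        "zeta_pos_mV",
        "zeta_neg_mV",
        "s_hydrophobic_A2",
        "s_hydrophilic_A2",
    ],
}

RESPONSE_COLUMN = "response_percent"
COLLINEARITY_TOL = 1e-10


@dataclass
class RegressionFit:
    """OLS fit report: coefficients with inference and standardized betas."""

    variable_names: list[str]  # includes "intercept" first
    coefficients: np.ndarray
    standard_errors: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    r_squared: float
    n: int
    variant: str = ""
    encoding: str = "magnitude"
    standardized_coefficients: pd.Series | None = None

    def __post_init__(self) -> None:
        k = len(self.variable_names)
        for arr in (self.coefficients, self.standard_errors, self.t_values, self.p_values):
            if len(arr) != k:
                raise ValueError("inconsistent lengths in RegressionFit fields")

    def coefficient_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": self.variable_names,
                "coefficient": self.coefficients,
                "se": self.standard_errors,
                "t": self.t_values,
                "p": self.p_values,
            }
        )

    def params(self) -> pd.Series:
        return pd.Series(self.coefficients, index=self.variable_names)


def split_zeta(zeta: float, encoding: str = "magnitude") -> tuple[float, float]:
    """Split a signed zeta potential into (ζpos, ζneg) features.

    ``magnitude`` (default): ζ<0 → (0, |ζ|), both features non-negative.
    ``signed``: ζ<0 → (0, ζ), the negative feature keeps its sign.
    The two encodings span the same model space; the ζneg coefficient
    flips sign between them.
    """
    if not np.isfinite(zeta):
        raise ValueError("zeta must be finite")
    if encoding not in ("magnitude", "signed"):
        raise ValueError(f"unknown zeta encoding {encoding!r}")
    if zeta > 0:
        return float(zeta), 0.0
    if zeta < 0:
        return 0.0, float(-zeta if encoding == "magnitude" else zeta)
    return 0.0, 0.0


def merge_conditions_descriptors(
    conditions: pd.DataFrame, descriptors: pd.DataFrame
) -> pd.DataFrame:
    """Join the condition table (per serotype × surface × buffer) with the
    per-serotype capsid descriptor table."""
    keys = ["serotype", "surface_id", "buffer_id"]
    dup = conditions.duplicated(subset=keys)
    if dup.any():
        raise ValueError(
            f"duplicate condition keys: {conditions.loc[dup, keys].to_dict('records')}"
        )
    if descriptors["serotype"].duplicated().any():
        raise ValueError("duplicate serotype in descriptor table")
    unknown = set(conditions["serotype"]) - set(descriptors["serotype"])
    if unknown:
        raise KeyError(f"serotypes without descriptors: {sorted(unknown)}")
    desc = descriptors.rename(
        columns={
            "sasa_hydrophobic_A2": "s_hydrophobic_A2",
            "sasa_hydrophilic_A2": "s_hydrophilic_A2",
        }
    )[["serotype", "s_hydrophobic_A2", "s_hydrophilic_A2"]]
    return conditions.merge(desc, on="serotype", how="left", validate="many_to_one")


def build_design(
    rows: pd.DataFrame, variant: str = "final", encoding: str = "magnitude"
) -> tuple[pd.DataFrame, pd.Series]:
    """Feature matrix and response for one model variant.

    ``rows`` must carry theta_deg, zeta_mV, response_percent, and for the
    final variant also s_hydrophobic_A2 / s_hydrophilic_A2 (e.g. from
    :func:`merge_conditions_descriptors`).  The intercept is added at fit
    time, not here.
    """
    if variant not in VARIANT_COLUMNS:
        raise ValueError(f"unknown variant {variant!r}; choose from {list(VARIANT_COLUMNS)}")
    df = rows.copy()
    split = np.array([split_zeta(z, encoding) for z in df["zeta_mV"]])
    df["zeta_pos_mV"], df["zeta_neg_mV"] = split[:, 0], split[:, 1]
    cols = VARIANT_COLUMNS[variant]
    missing = [c for c in cols + [RESPONSE_COLUMN] if c not in df.columns]
    if missing:
        raise KeyError(f"design rows missing columns: {missing}")
    X = df[cols].astype(float).reset_index(drop=True)
    y = df[RESPONSE_COLUMN].astype(float).reset_index(drop=True)
    return X, y


def _check_design(X: pd.DataFrame, y: pd.Series) -> None:
    n, k = X.shape
    if n <= k + 1:
        raise ValueError(f"need more than {k + 1} rows to fit {k} predictors, got {n}")
    with_const = np.column_stack([np.ones(n), X.to_numpy(dtype=float)])
    sv = np.linalg.svd(with_const, compute_uv=False)
    if sv[-1] < COLLINEARITY_TOL * sv[0]:
        corr = np.corrcoef(X.to_numpy(dtype=float), rowvar=False)
        pairs = [
            (X.columns[i], X.columns[j])
            for i in range(k)
            for j in range(i + 1, k)
            if abs(corr[i, j]) > 1 - 1e-8
        ]
        const_cols = [c for c in X.columns if X[c].nunique() == 1]
        raise ValueError(
            f"singular design; collinear column pairs: {pairs or 'n/a'}; "
            f"constant columns: {const_cols or 'n/a'}"
        )


def fit_ols(
    X: pd.DataFrame,
    y: pd.Series,
    variant: str = "",
    encoding: str = "magnitude",
) -> RegressionFit:
    """Ordinary least squares with intercept; t and two-sided p per
    coefficient (df = n − k − 1), R² about the response mean."""
    _check_design(X, y)
    model = sm.OLS(np.asarray(y, dtype=float), sm.add_constant(X.to_numpy(dtype=float)))
    res = model.fit()
    names = ["intercept"] + list(X.columns)
    # constant response: SStot = 0 and statsmodels reports -inf; the
    # null fit explains nothing, so report R² = 0
    r_squared = float(res.rsquared) if np.isfinite(res.rsquared) else 0.0
    return RegressionFit(
        variable_names=names,
        coefficients=np.asarray(res.params),
        standard_errors=np.asarray(res.bse),
        t_values=np.asarray(res.tvalues),
        p_values=np.asarray(res.pvalues),
        r_squared=r_squared,
        n=int(res.nobs),
        variant=variant,
        encoding=encoding,
    )


def standardized_fit(X: pd.DataFrame, y: pd.Series) -> pd.Series:
    """Standardized regression coefficients: z-score every predictor and
    the response (sample sd, n−1) and refit.

    Equivalent to βstd_j = β_j · sd(x_j) / sd(y); comparable across
    predictors with different units.
    """
    sx = X.std(ddof=1)
    sy = float(np.std(y, ddof=1))
    zero = list(sx.index[sx == 0])
    if zero or sy == 0:
        raise ValueError(f"zero-variance columns cannot be standardized: {zero or ['response']}")
    Z = (X - X.mean()) / sx
    zy = (np.asarray(y, dtype=float) - float(np.mean(y))) / sy
    res = sm.OLS(zy, sm.add_constant(Z.to_numpy(dtype=float))).fit()
    return pd.Series(np.asarray(res.params)[1:], index=list(X.columns), name="standardized")


def fit_model(
    rows: pd.DataFrame, variant: str = "final", encoding: str = "magnitude"
) -> RegressionFit:
    """Convenience: build design, fit OLS and attach standardized betas."""
    X, y = build_design(rows, variant=variant, encoding=encoding)
    fit = fit_ols(X, y, variant=variant, encoding=encoding)
    fit.standardized_coefficients = standardized_fit(X, y)
    return fit


def predict(fit: RegressionFit, new_rows: pd.DataFrame) -> pd.DataFrame:
    """Linear prediction for new condition rows.

    Returns both the raw linear predictor and its [0, 100] % clamp; the
    assay cannot observe values outside that range.
    """
    df = new_rows.copy()
    if "zeta_mV" in df.columns and "zeta_pos_mV" not in df.columns:
        split = np.array([split_zeta(z, fit.encoding) for z in df["zeta_mV"]])
        df["zeta_pos_mV"], df["zeta_neg_mV"] = split[:, 0], split[:, 1]
    needed = fit.variable_names[1:]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise KeyError(f"new rows missing fitted variables: {missing}")
    raw = fit.coefficients[0] + df[needed].to_numpy(dtype=float) @ fit.coefficients[1:]
    out = df.reset_index(drop=True).copy()
    out["predicted_percent_raw"] = raw
    out["predicted_percent"] = np.clip(raw, 0.0, 100.0)
    return out


def validation_r2(
    observed, predicted, definition: str = "pearson_squared"
) -> float:
    """Agreement between measured and predicted adsorption ratios.

    ``pearson_squared``: squared Pearson correlation (scale-free).
    ``one_minus_ssres``: 1 − SSres/SStot about the observed mean (can be
    negative for a bad predictor).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be equal-length vectors")
    if obs.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(obs) == 0:
        raise ValueError("zero variance in observed values")
    if definition == "pearson_squared":
        if np.std(pred) == 0:
            raise ValueError("pearson_squared undefined for a constant predictor")
        return float(np.corrcoef(obs, pred)[0, 1] ** 2)
    if definition == "one_minus_ssres":
        ss_res = float(np.sum((obs - pred) ** 2))
        ss_tot = float(np.sum((obs - obs.mean()) ** 2))
        return 1.0 - ss_res / ss_tot
    raise ValueError(f"unknown R² definition {definition!r}")
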