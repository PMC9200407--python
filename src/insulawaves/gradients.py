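"""Spatial gradient statistics along the anterior-posterior and
superior-inferior axes.

For each hemisphere separately, a per-electrode spectral measure (peak
frequency or peak power in a band) is regressed on the electrode's y (AP)
and z (SI) coordinates with subject as a categorical covariate and the
pairwise interactions:

    EPHYS = b0 + bAP*y + bSI*z + bSUBJ + (y x z) + (y x SUBJ) + (z x SUBJ)

The model is an ordinary least-squares fit with subject dummies (a
random-intercept mixed model is available behind ``mixed=True`` for
sensitivity).  The reported t statistics for bAP and bSI quantify the
direction and strength of the spatial gradients; Benjamini-Hochberg FDR
correction is applied across the reported terms.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests


@dataclasses.dataclass
class GradientFit:
    dependent: str
    hemisphere: str | None
    table: pd.DataFrame          # term, estimate, t, p, q
    df_resid: float
    n: int
    t_ap: float
    p_ap: float
    t_si: float
    p_si: float
    single_subject: bool = False


def _design(y: np.ndarray, z: np.ndarray, subjects: np.ndarray
            ) -> tuple[np.ndarray, list[str], bool]:
    """Design matrix for the gradient formula.

    Coordinates are centered and the subject factor is sum-coded, so the
    AP/SI main effects are the average slopes across subjects at the mean
    coordinate — invariant to adding a constant to all coordinates and to
    subject relabeling.  Subject terms are dropped when only one subject
    is present.
    """

    y = y - y.mean()
    z = z - z.mean()
    cols = [np.ones_like(y), y, z, y * z]
    names = ["intercept", "AP", "SI", "AP:SI"]
    levels = sorted(set(subjects))
    single = len(levels) < 2
    if not single:
        last = levels[-1]
        for lev in levels[:-1]:
            d = np.where(subjects == lev, 1.0,
                         np.where(subjects == last, -1.0, 0.0))
            cols += [d, y * d, z * d]
            names += [f"subj[{lev}]", f"AP:subj[{lev}]", f"SI:subj[{lev}]"]
    return np.column_stack(cols), names, single


def fit_gradient_model(values: pd.Series | np.ndarray,
                       electrodes: pd.DataFrame,
                       hemisphere: str | None = None,
                       dependent: str = "value",
                       mixed: bool = False) -> GradientFit:
    """Fit the gradient model for one measure in one hemisphere.

    ``values`` must align with the rows of ``electrodes`` (one value per
    electrode; NaNs are dropped).  With ``hemisphere`` given, only that
    hemisphere's electrodes enter the fit.
    """

    values = np.asarray(values, dtype=float)
    if len(values) != len(electrodes):
        raise ValueError("values must align with electrode table rows")
    tab = electrodes.reset_index(drop=True)
    keep = np.isfinite(values)
    if hemisphere is not None:
        keep &= (tab["hemisphere"] == hemisphere).to_numpy()
    tab = tab[keep]
    vals = values[keep]
    y = tab["y"].to_numpy(dtype=float)
    z = tab["z"].to_numpy(dtype=float)
    subjects = tab["subject"].to_numpy()
    X, names, single = _design(y, z, subjects)
    if single:
        warnings.warn("single subject: fitting without subject terms")
    if len(vals) < X.shape[1] + 1:
        raise ValueError("too few electrodes for the model terms")

    if mixed and not single:
        yc, zc = y - y.mean(), z - z.mean()
        md = sm.MixedLM(vals, np.column_stack([np.ones_like(yc), yc, zc,
                                               yc * zc]),
                        groups=subjects)
        res = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for method in (None, ["powell"], ["nm"]):
                try:
                    res = md.fit(reml=True) if method is None else \
                        md.fit(reml=True, method=method)
                    break
                except np.linalg.LinAlgError:
                    continue
        if res is None:
            raise np.linalg.LinAlgError(
                "mixed-model fit failed for every optimizer")
        names = ["intercept", "AP", "SI", "AP:SI"]
        est = res.fe_params
        tvals = res.tvalues[:len(names)]
        pvals = res.pvalues[:len(names)]
        df_resid = float(len(vals) - len(names))
    else:
        res = sm.OLS(vals, X).fit()
        est, tvals, pvals = res.params, res.tvalues, res.pvalues
        df_resid = float(res.df_resid)

    table = pd.DataFrame({
        "term": names, "estimate": np.asarray(est),
        "t": np.asarray(tvals), "p": np.asarray(pvals)})
    table["q"] = fdr_correct(table["p"].to_numpy())
    i_ap = names.index("AP")
    i_si = names.index("SI")
    return GradientFit(
        dependent=dependent, hemisphere=hemisphere, table=table,
        df_resid=df_resid, n=len(vals),
        t_ap=float(tvals[i_ap]), p_ap=float(pvals[i_ap]),
        t_si=float(tvals[i_si]), p_si=float(pvals[i_si]),
        single_subject=single)


def fdr_correct(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values."""

    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def gradient_table(fits: list[GradientFit]) -> pd.DataFrame:
    """Long-format TSV-ready table across band x measure x hemisphere fits."""

    rows = []
    for f in fits:
        for _, r in f.table.iterrows():
            rows.append({
                "dependent": f.dependent, "hemisphere": f.hemisphere,
                "term": r["term"], "estimate": r["estimate"],
                "t": r["t"], "df": f.df_resid, "p": r["p"], "q": r["q"]})
    return pd.DataFrame(rows)
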