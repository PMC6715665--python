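"""Summaries and heterogeneous-variance repeated-measures inference.

The design follows the study's analysis plan: a two-way repeated-measures
model with anatomical segment and heart cycle as factors and animal as a
block, allowing a different residual variance per segment.  It is fitted
by iterative feasible generalized least squares (FGLS): alternate
(a) weighted least squares given the current per-segment variances and
(b) re-estimation of those variances from the weighted-fit residuals,
until the variances stabilize.  Segment pairs are then compared with
post hoc Wald z-tests on the FGLS coefficient covariance.

With equal true variances the scheme collapses to ordinary least squares,
which is exercised as an invariant in the test suite.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ModelError, ValidationError

FGLS_TOL = 1e-8
FGLS_MAX_ITER = 50
TABLE_COLUMNS = ("animal", "segment", "beat", "value")


def make_table(animal, segment, beat, value) -> pd.DataFrame:
    """Assemble and validate a long-format measurement table."""
    df = pd.DataFrame({"animal": animal, "segment": segment, "beat": beat, "value": value})
    if df.duplicated(["animal", "segment", "beat"]).any():
        raise ValidationError("duplicate (animal, segment, beat) rows")
    return df


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SD per segment label: beats averaged within animal first,
    then mean and sample SD (n-1) across animals.

    A label observed in a single animal gets SD = NaN and ``sd_defined``
    False.
    """
    if table.empty:
        raise ValidationError("summarize: empty table")
    per_animal = table.groupby(["segment", "animal"])["value"].mean().reset_index()
    rows = []
    for label, sub in per_animal.groupby("segment"):
        vals = sub["value"].to_numpy()
        rows.append(
            {
                "segment": label,
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
                "n_animals": int(vals.size),
                "sd_defined": vals.size > 1,
            }
        )
    return pd.DataFrame(rows)


def percent_expansion(max_val: float, min_val: float) -> float:
    """Relative amplitude 100 * (max - min) / min, in percent."""
    if min_val <= 0:
        raise ValidationError("percent_expansion requires min_val > 0")
    return 100.0 * (max_val - min_val) / min_val


@dataclass
class RmAnovaResult:
    """FGLS fit of value ~ segment + cycle + animal-block."""

    params: pd.Series            # named coefficients
    cov: pd.DataFrame            # coefficient covariance (final weighted fit)
    segment_levels: list
    segment_effects: dict        # level -> effect relative to the reference level
    resid_var: dict              # segment -> residual variance
    converged: bool
    n_iter: int
    notes: tuple = ()

    def effect_vector(self, level) -> np.ndarray:
        """Coefficient-space contrast vector selecting a segment effect."""
        v = np.zeros(len(self.params))
        name = f"segment[{level}]"
        if name in self.params.index:
            v[self.params.index.get_loc(name)] = 1.0
        return v


def _design(table: pd.DataFrame, drop_animal: bool):
    seg = pd.Categorical(table["segment"])
    cyc = pd.Categorical(table["beat"])
    cols, names = [np.ones(len(table))], ["Intercept"]
    for level in seg.categories[1:]:
        cols.append((seg == level).astype(float))
        names.append(f"segment[{level}]")
    for level in cyc.categories[1:]:
        cols.append((cyc == level).astype(float))
        names.append(f"cycle[{level}]")
    if not drop_animal:
        ani = pd.Categorical(table["animal"])
        for level in ani.categories[1:]:
            cols.append((ani == level).astype(float))
            names.append(f"animal[{level}]")
    return np.column_stack(cols), names, np.asarray(seg), list(seg.categories)


def fit_rm_model(table: pd.DataFrame) -> RmAnovaResult:
    """Fit the repeated-measures model with segment-specific residual variance.

    Starts from OLS, then iterates WLS with weights 1 / sigma^2_segment and
    per-segment variance re-estimation until the relative change in every
    variance falls below 1e-8 (at most 50 iterations).  The coefficient
    covariance is (X' W X)^-1 from the final weighted fit.
    """
    for col in TABLE_COLUMNS:
        if col not in table.columns:
            raise ValidationError(f"measurement table missing column {col!r}")
    n_seg = table["segment"].nunique()
    if n_seg < 2:
        raise ModelError("need >= 2 segments")
    if table["beat"].nunique() < 2:
        raise ModelError("need >= 2 cycles")
    n_animals = table["animal"].nunique()
    notes = ("animal entered as fixed block",)
    drop_animal = n_animals < 2
    if drop_animal:
        notes = ("single animal: block factor dropped",)

    X, names, seg_codes, seg_levels = _design(table, drop_animal)
    y = table["value"].to_numpy(dtype=float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ModelError("singular design matrix")

    groups = [seg_codes == lv for lv in seg_levels]
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    sigma2 = _group_variances(y - X @ beta, groups, seg_levels, n, p)
    converged = False
    for it in range(1, FGLS_MAX_ITER + 1):
        w = np.empty(n)
        for g, lv in zip(groups, seg_levels):
            w[g] = 1.0 / sigma2[lv]
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        new = _group_variances(y - X @ beta, groups, seg_levels, n, p)
        rel = max(abs(new[lv] - sigma2[lv]) / sigma2[lv] for lv in seg_levels)
        sigma2 = new
        if rel < FGLS_TOL:
            converged = True
            break
    if not converged:
        notes = notes + ("FGLS did not converge",)

    w = np.empty(n)
    for g, lv in zip(groups, seg_levels):
        w[g] = 1.0 / sigma2[lv]
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    params = pd.Series(beta, index=names)
    effects = {seg_levels[0]: 0.0}
    for lv in seg_levels[1:]:
        effects[lv] = float(params[f"segment[{lv}]"])
    return RmAnovaResult(
        params=params,
        cov=pd.DataFrame(cov, index=names, columns=names),
        segment_levels=seg_levels,
        segment_effects=effects,
        resid_var=sigma2,
        converged=converged,
        n_iter=it,
        notes=notes,
    )


def _group_variances(resid, groups, levels, n, p) -> dict:
    """Per-segment residual variance with group-prorated df correction."""
    out = {}
    for g, lv in zip(groups, levels):
        ng = int(g.sum())
        df = max(ng - p * ng / n, 1.0)
        out[lv] = float((resid[g] ** 2).sum() / df)
    # exactly-fitting groups get a tiny positive floor so weights stay finite
    floor = max(1e-12 * max(out.values()), 1e-24)
    return {lv: max(v, floor) for lv, v in out.items()}


def pairwise_wald(result: RmAnovaResult) -> pd.DataFrame:
    """Post hoc Wald z-tests for all segment pairs.

    z = (effect difference) / SE(difference) with the SE from the FGLS
    coefficient covariance; two-sided p from the standard normal.  A zero
    SE flags the contrast as degenerate instead of producing an infinite z.
    """
    cov = result.cov.to_numpy()
    rows = []
    for a, b in itertools.combinations(result.segment_levels, 2):
        L = result.effect_vector(b) - result.effect_vector(a)
        est = float(result.segment_effects[b] - result.segment_effects[a])
        var = float(L @ cov @ L)
        se = np.sqrt(max(var, 0.0))
        degenerate = se == 0.0
        z = est / se if not degenerate else np.nan
        pval = float(2.0 * sps.norm.sf(abs(z))) if not degenerate else np.nan
        rows.append(
            {
                "pair": f"{a} vs {b}",
                "estimate": est,
                "se": float(se),
                "z": float(z) if not degenerate else np.nan,
                "p": pval,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)
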