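"""Group statistics: adjusted comparisons, FDR, and partial correlations.

The group contrast is a two-sample comparison with age and gender controlled,
operationalised as the group term of an additive least-squares model
``y ~ group + age + gender``; its t statistic carries n - 4 degrees of freedom
and adjusted group means are evaluated at grand-mean covariates.  Multiple
testing is handled by Benjamini-Hochberg FDR within explicit families (the 90
nodal tests of one network kind form one family, the global metrics of one
network kind another, each clinical variable's 90 correlations another).
Partial correlation residualises both variables on the covariates (with
intercept) and correlates the residuals; its p-value uses
t = r * sqrt(df / (1 - r^2)) with df = n - 2 - k.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests


GLOBAL_METRIC_NAMES = ("Eg", "Cp", "Eloc", "Lp", "sigma")


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def ks_normality(values: np.ndarray) -> tuple[float, float]:
    """Kolmogorov-Smirnov normality screen with Lilliefors correction.

    The null's mean and SD are estimated from the sample, so the classical KS
    distribution would be anti-conservative; the Lilliefors table corrects it.
    Advisory only: nothing downstream is gated on the outcome.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("normality screen needs at least 4 observations")
    if np.ptp(v) == 0:
        raise ValueError("constant sample: normality test undefined")
    stat, p = lilliefors(v, dist="norm")
    return float(stat), float(p)


def adjusted_group_compare(
    y: np.ndarray, group: np.ndarray, age: np.ndarray, gender: np.ndarray
) -> tuple[float, float, dict[str, float]]:
    """Two-group comparison with age and gender controlled.

    ``group`` is 1 for patients and 0 for controls (any 0/1 coding works);
    ``gender`` is a 0/1 indicator.  Returns ``(t, p, adjusted_means)`` where the
    adjusted means are model predictions for each group at grand-mean
    covariates.  Reduces exactly to the classical pooled two-sample t test when
    the covariates are constant.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(group, dtype=float)
    n = y.size
    groups = np.unique(g)
    if groups.size != 2:
        raise ValueError("both groups must be non-empty")
    x = np.column_stack([np.ones(n), g, np.asarray(age, float),
                         np.asarray(gender, float)])
    # drop covariate columns with no variation (they alias the intercept)
    keep = [0, 1] + [c for c in (2, 3) if np.ptp(x[:, c]) > 0]
    x = x[:, keep]
    k = x.shape[1]
    if np.linalg.matrix_rank(x) < k:
        raise ValueError("rank-deficient design: group confounded with covariates")
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    df = n - k
    if df <= 0:
        raise ValueError("not enough observations for the adjusted comparison")
    s2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(x.T @ x)
    se = np.sqrt(s2 * xtx_inv[1, 1])
    t = float(beta[1] / se)
    p = float(2 * sps.t.sf(abs(t), df))
    base = x.mean(axis=0)
    means = {}
    for label, gv in (("group0", groups[0]), ("group1", groups[1])):
        row = base.copy()
        row[1] = gv
        means[label] = float(row @ beta)
    return t, p, means


def fdr_bh(p_values, q_level: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and rejection flags."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=q_level, method="fdr_bh")
    return q, reject


def partial_correlation(x, y, covariates) -> tuple[float, int, float]:
    """Partial correlation of x and y given a covariate matrix.

    Residualises both variables on ``covariates`` (n x k, intercept added) and
    returns the Pearson correlation of the residuals with df = n - 2 - k.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(covariates, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    n, k = z.shape[0], z.shape[1]
    if x.size != n or y.size != n:
        raise ValueError("x, y and covariates must have matching length")
    df = n - 2 - k
    if df <= 0:
        raise ValueError(f"insufficient degrees of freedom (n={n}, k={k})")
    design = np.column_stack([np.ones(n), z])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    sx, sy = np.sqrt(rx @ rx), np.sqrt(ry @ ry)
    if (sx <= 1e-10 * max(1.0, float(np.abs(x).max()))
            or sy <= 1e-10 * max(1.0, float(np.abs(y).max()))):
        raise ValueError("zero residual variance: partial correlation undefined")
    r = float(np.clip((rx @ ry) / (sx * sy), -1.0, 1.0))
    if abs(r) == 1.0:
        return r, df, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = float(2 * sps.t.sf(abs(t), df))
    return r, df, p


# ---------------------------------------------------------------------------
# cohort-level drivers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComparisonResult:
    target: str          # metric name
    region: str          # region abbreviation or "GLOBAL"
    network_kind: str
    lobe: str            # "" for global metrics
    adjusted_mean_patient: float
    adjusted_mean_control: float
    group_t: float
    p: float
    q: float = float("nan")
    significant: bool = False
    family_id: str = ""


@dataclass(frozen=True)
class CorrelationResult:
    region: str
    clinical_variable: str
    covariates: tuple[str, ...]
    r: float
    df: int
    p: float
    q: float = float("nan")
    significant: bool = False
    family_id: str = ""


def _design_from_subjects(subjects: pd.DataFrame):
    group = (subjects["group"] == "patient").to_numpy(float)
    age = subjects["age"].to_numpy(float)
    gender = (subjects["gender"] == "male").to_numpy(float)
    return group, age, gender


def compare_all(global_table: pd.DataFrame, nodal_table: pd.DataFrame,
                subjects: pd.DataFrame, atlas, q_level: float = 0.05
                ) -> list[ComparisonResult]:
    """Adjusted group comparison of every topological property.

    ``global_table``: columns subject_id, network_kind, metric, value (metrics
    Eg/Cp/Eloc/Lp/sigma).  ``nodal_table``: columns subject_id, network_kind,
    region (1-based index), Enodal.  FDR families: all global metrics of one
    network kind together; the 90 nodal tests of one network kind together.
    """
    subjects = subjects.set_index("subject_id")
    results: list[ComparisonResult] = []
    families: dict[str, list[int]] = {}

    def run_one(values: pd.Series, target: str, region: str, kind: str,
                lobe: str, family: str) -> None:
        sub = subjects.loc[values.index]
        group, age, gender = _design_from_subjects(sub.reset_index())
        t, p, means = adjusted_group_compare(values.to_numpy(float), group,
                                             age, gender)
        results.append(ComparisonResult(
            target, region, kind, lobe,
            adjusted_mean_patient=means["group1"],
            adjusted_mean_control=means["group0"],
            group_t=t, p=p, family_id=family))
        families.setdefault(family, []).append(len(results) - 1)

    for kind, sub_g in global_table.groupby("network_kind"):
        family = f"global:{kind}"
        for metric in GLOBAL_METRIC_NAMES:
            rows = sub_g[sub_g["metric"] == metric]
            if rows.empty:
                continue
            values = rows.set_index("subject_id")["value"]
            run_one(values, metric, "GLOBAL", str(kind), "", family)

    abbrev = atlas.table["abbreviation"]
    lobes = atlas.table["lobe"]
    for kind, sub_n in nodal_table.groupby("network_kind"):
        family = f"nodal:{kind}"
        for region, rows in sub_n.groupby("region"):
            values = rows.set_index("subject_id")["Enodal"]
            run_one(values, "Enodal", str(abbrev.loc[region]), str(kind),
                    str(lobes.loc[region]), family)

    # FDR within each family
    out = list(results)
    for family, idx in families.items():
        q, reject = fdr_bh([results[i].p for i in idx], q_level)
        for j, i in enumerate(idx):
            r = results[i]
            out[i] = ComparisonResult(
                r.target, r.region, r.network_kind, r.lobe,
                r.adjusted_mean_patient, r.adjusted_mean_control,
                r.group_t, r.p, q=float(q[j]), significant=bool(reject[j]),
                family_id=family)
    return out


CLINICAL_VARIABLES = ("duration", "verbal_iq", "performance_iq")


def correlate_clinical(nodal_table: pd.DataFrame, subjects: pd.DataFrame,
                       atlas, q_level: float = 0.05,
                       network_kind: str = "FA_wei") -> list[CorrelationResult]:
    """Partial correlation of nodal efficiency with clinical variables.

    Patients only, weighted network only.  Covariates: age and gender; the
    duration analysis additionally controls age at seizure onset.  FDR is
    applied per clinical variable across the 90 regions.
    """
    patients = subjects[subjects["group"] == "patient"].set_index("subject_id")
    if patients.empty:
        raise ValueError("no patient records")
    nod = nodal_table[nodal_table["network_kind"] == network_kind]
    nod = nod[nod["subject_id"].isin(patients.index)]
    abbrev = atlas.table["abbreviation"]

    results: list[CorrelationResult] = []
    for var in CLINICAL_VARIABLES:
        cov_names = ["age", "gender"] + (["onset"] if var == "duration" else [])
        block: list[CorrelationResult] = []
        for region, rows in nod.groupby("region"):
            rows = rows.set_index("subject_id")
            sub = patients.loc[rows.index]
            cov = np.column_stack([
                sub["age"].to_numpy(float),
                (sub["gender"] == "male").to_numpy(float),
            ] + ([sub["onset"].to_numpy(float)] if var == "duration" else []))
            r, df, p = partial_correlation(
                rows["Enodal"].to_numpy(float), sub[var].to_numpy(float), cov)
            block.append(CorrelationResult(
                str(abbrev.loc[region]), var, tuple(cov_names), r, df, p,
                family_id=f"correlation:{var}"))
        q, reject = fdr_bh([b.p for b in block], q_level)
        for b, qv, rej in zip(block, q, reject):
            results.append(CorrelationResult(
                b.region, b.clinical_variable, b.covariates, b.r, b.df, b.p,
                q=float(qv), significant=bool(rej), family_id=b.family_id))
    return results


def comparison_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def correlation_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
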