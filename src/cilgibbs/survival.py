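"""Survival ordering of the mean inhibition metric (MIM).

MIM = (z_L + z_G)/2 collapses the per-patient inhibition metric to one
dimension.  Within a group, patients are ordered by increasing survival
time and the MIM sequence is Loess-smoothed; the same is done under a
randomised ordering as a null baseline.  If convergence of the Gibbs
model really tracks survival, the survival-ordered smooth should sit
inside a band around the group's randomised k-means centroid level while
the randomised smooth wanders — a 2x2 Fisher exact test quantifies this.
The first index from which the survival-ordered smooth stays inside the
band marks where homotypic contact inhibition is established; patients
below that survival time form the LH-CIL (lost heterotypic CIL)
subgroup, the rest H-CIL.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = ["MIMSeries", "BandTest", "compute_mim", "loess_smooth",
           "ordered_series", "band_association", "establishment_point",
           "km_logrank", "split_cil", "fisher_exact_2x2"]


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table by direct enumeration.

    Conditional on the margins, the count in cell (0, 0) is
    hypergeometric; the two-sided p-value sums the probabilities of all
    tables at most as probable as the observed one.  Ties are compared
    with a relative guard of 1e-7 (the usual convention) so equally
    probable tables on the other tail are included despite round-off.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if t.sum() == 0:
        return 1.0  # degenerate empty table: a single possible outcome
    a = t[0, 0]
    m1 = t[0].sum()          # first row margin
    n_total = t.sum()
    k = t[:, 0].sum()        # first column margin
    support = np.arange(max(0, k - (n_total - m1)), min(k, m1) + 1)
    pmf = hypergeom.pmf(support, n_total, m1, k)
    p_obs = pmf[support == a][0]
    return float(min(1.0, pmf[pmf <= p_obs * (1.0 + 1e-7)].sum()))


def compute_mim(record) -> float | np.ndarray:
    """Mean inhibition metric (z_L + z_G) / 2 of a record or frame."""
    if isinstance(record, pd.DataFrame):
        if not {"z_L_r", "z_G_r"} <= set(record.columns):
            raise ValueError("records need z_L_r and z_G_r columns")
        return (record["z_L_r"] + record["z_G_r"]).to_numpy() / 2.0
    z_l = record.get("z_L_r") if hasattr(record, "get") else record["z_L_r"]
    z_g = record.get("z_G_r") if hasattr(record, "get") else record["z_G_r"]
    if z_l is None or z_g is None:
        raise ValueError("record is missing a z-scored coordinate")
    return (z_l + z_g) / 2.0


def loess_smooth(values, span: float = 0.3) -> np.ndarray:
    """Local linear regression with tricube weights over index position.

    Exact on linear inputs; errors if the span covers fewer than 3 points
    (a local line needs at least 3 for a stable weighted fit).
    """
    y = np.asarray(values, dtype=float)
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 points to smooth")
    if not (0 < span <= 1):
        raise ValueError("span must lie in (0, 1]")
    if int(np.ceil(span * n)) < 3:
        raise ValueError("span too small: local window has < 3 points")
    x = np.arange(n, dtype=float)
    return lowess(y, x, frac=span, it=0, delta=0.0, return_sorted=False)


@dataclass
class MIMSeries:
    patient_ids: list
    raw: np.ndarray
    smoothed: np.ndarray
    ordering: str                  # increasing_survival | randomized
    span: float
    survival_days: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        assert len(self.raw) == len(self.smoothed) == len(self.patient_ids)


def ordered_series(records: pd.DataFrame, mode: str = "increasing_survival",
                   seed=None, span: float = 0.3) -> MIMSeries:
    """MIM series of a patient group under a survival or random ordering.

    ``increasing_survival`` sorts ascending by survival_days with ties
    broken by patient_id; ``randomized`` applies a seeded uniform
    permutation.  The MIM sequence is Loess-smoothed with the given span.
    """
    if mode not in ("increasing_survival", "randomized"):
        raise ValueError(f"unknown ordering mode {mode!r}")
    if records["survival_days"].isna().any():
        raise ValueError("survival_days missing for some records")
    df = records.sort_values(["survival_days", "patient_id"],
                             kind="stable").reset_index(drop=True)
    if mode == "randomized":
        rng = np.random.default_rng(seed)
        df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
    raw = compute_mim(df)
    return MIMSeries(
        patient_ids=df["patient_id"].tolist(), raw=raw,
        smoothed=loess_smooth(raw, span), ordering=mode, span=span,
        survival_days=df["survival_days"].to_numpy(dtype=float), seed=seed)


@dataclass
class BandTest:
    center: float
    sd: float
    multiplier: float
    table: np.ndarray            # rows: ordering; cols: inside/outside
    p_value: float
    inside_increasing: np.ndarray
    inside_randomized: np.ndarray


def band_association(smoothed_increasing, smoothed_randomized,
                     centroid_center: float, sd: float,
                     multiplier: float = 4.0) -> BandTest:
    """Fisher's exact association between ordering and band membership.

    Each smoothed value is classified as inside or outside
    [center - multiplier*sd, center + multiplier*sd]; the 2x2 table
    (ordering x membership) is tested two-sided via the hypergeometric
    distribution.
    """
    a = np.asarray(smoothed_increasing, dtype=float)
    b = np.asarray(smoothed_randomized, dtype=float)
    if len(a) != len(b):
        raise ValueError("series must have equal length")
    if sd * multiplier <= 0:
        raise ValueError("band has zero width")
    half = multiplier * sd
    in_a = np.abs(a - centroid_center) <= half
    in_b = np.abs(b - centroid_center) <= half
    table = np.array([
        [in_a.sum(), (~in_a).sum()],
        [in_b.sum(), (~in_b).sum()],
    ])
    p = fisher_exact_2x2(table)
    return BandTest(center=float(centroid_center), sd=float(sd),
                    multiplier=float(multiplier), table=table,
                    p_value=float(p), inside_increasing=in_a,
                    inside_randomized=in_b)


def establishment_point(smoothed_increasing, band: BandTest,
                        survival_sorted) -> tuple[int | None, float | None]:
    """First index from which the smooth stays inside the band for good.

    Returns (index, survival_days at that index); (None, None) when the
    series never settles inside the band ("not established").
    """
    a = np.asarray(smoothed_increasing, dtype=float)
    t = np.asarray(survival_sorted, dtype=float)
    half = band.multiplier * band.sd
    inside = np.abs(a - band.center) <= half
    if not inside[-1]:
        return None, None
    # last index of an outside value, +1
    outside = np.flatnonzero(~inside)
    idx = 0 if len(outside) == 0 else int(outside[-1]) + 1
    return idx, float(t[idx])


def split_cil(records: pd.DataFrame, establishment_days: float) -> pd.Series:
    """Partition a group into LH-CIL (survival below the establishment
    time) and H-CIL (at or above).  Every patient is assigned."""
    t = records["survival_days"].to_numpy(dtype=float)
    return pd.Series(np.where(t < establishment_days, "LH-CIL", "H-CIL"),
                     index=records.index, name="cil_subgroup")


def associate_group(records: pd.DataFrame, group_centroid,
                    span: float = 0.3, multiplier: float = 4.0,
                    seed=None) -> dict:
    """Full MIM-vs-survival association for one patient group.

    Builds the survival-ordered and randomized smoothed MIM series, a
    band centred on the group's k-means centroid collapsed to the MIM
    scale (half-width = multiplier x SD of the randomized smooth), the
    Fisher band test, the establishment point and the LH-CIL / H-CIL
    split.  Returns a dict bundle.
    """
    inc = ordered_series(records, "increasing_survival", span=span)
    rnd = ordered_series(records, "randomized", seed=seed, span=span)
    center = float(np.mean(np.asarray(group_centroid, dtype=float)))
    sd = float(np.std(rnd.smoothed))
    band = band_association(inc.smoothed, rnd.smoothed, center, sd,
                            multiplier)
    idx, days = establishment_point(inc.smoothed, band, inc.survival_days)
    sorted_records = records.sort_values(
        ["survival_days", "patient_id"], kind="stable").reset_index(drop=True)
    subgroup = (split_cil(sorted_records, days)
                if days is not None else None)
    return {
        "increasing": inc,
        "randomized": rnd,
        "band": band,
        "establishment_index": idx,
        "establishment_days": days,
        "established": idx is not None,
        "sorted_records": sorted_records,
        "cil_subgroup": subgroup,
    }


def km_logrank(records: pd.DataFrame, group_col: str = "group"):
    """Kaplan-Meier curves per group plus the two-group log-rank test.

    Returns (fitters, stat, p, reliable) where ``fitters`` maps group name
    to a fitted lifelines KaplanMeierFitter.  If either group has no
    observed events the test result is flagged unreliable.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    groups = records[group_col].unique()
    if len(groups) != 2:
        raise ValueError("exactly 2 non-empty groups required")
    fitters = {}
    for g in groups:
        sub = records[records[group_col] == g]
        if len(sub) == 0:
            raise ValueError(f"group {g!r} is empty")
        kmf = KaplanMeierFitter(label=str(g))
        kmf.fit(sub["survival_days"], event_observed=sub["event"])
        fitters[g] = kmf
    g0 = records[records[group_col] == groups[0]]
    g1 = records[records[group_col] == groups[1]]
    res = logrank_test(g0["survival_days"], g1["survival_days"],
                       event_observed_A=g0["event"],
                       event_observed_B=g1["event"])
    reliable = bool(g0["event"].sum() > 0 and g1["event"].sum() > 0)
    return fitters, float(res.test_statistic), float(res.p_value), reliable
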