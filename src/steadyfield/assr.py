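"""ASSR-level analyses: ROI selection, activation maxima, group statistics.

The region of interest is the 30 vertices with the highest metric values —
either in the pooled child sample ("common" mode, both groups averaged
together) or per subject ("individual" mode).  Activation maxima carry the
vertex's stored MNI coordinates and are excluded from coordinate analyses
when the metric does not exceed the noise floor (ITPC <= 0.18 by default,
the maximal baseline ITPC observed across subjects).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats as sfstats

logger = logging.getLogger("steadyfield")

__all__ = [
    "ROISelection",
    "ActivationMaximum",
    "ITPC_EXCLUSION_THRESHOLD",
    "select_roi",
    "locate_activation_maximum",
    "compare_assr_groups",
    "pointwise_timecourse_test",
]

#: Subjects whose peak ITPC does not exceed this value are excluded from
#: coordinate analyses (maximal baseline ITPC across subjects and conditions).
ITPC_EXCLUSION_THRESHOLD = 0.18

ROI_SIZE = 30


@dataclass
class ROISelection:
    """A fixed-size set of top-metric vertices."""

    mode: str                     # "common" | "individual"
    metric: str
    vertex_ids: np.ndarray
    hemisphere: str
    provenance: str = ""
    roi_size: int = ROI_SIZE

    def __post_init__(self) -> None:
        ids = np.asarray(self.vertex_ids)
        if ids.size != self.roi_size:
            raise ValueError(f"ROI must contain exactly {self.roi_size} vertices")
        if np.unique(ids).size != ids.size:
            raise ValueError("ROI vertex ids must be unique")


@dataclass
class ActivationMaximum:
    """Argmax vertex of a per-vertex metric map, with exclusion bookkeeping."""

    vertex_id: int
    coords: np.ndarray
    value: float
    included: bool
    reason: str = ""


def _top_k(values: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest values; ties broken by lower vertex id."""
    ids = np.arange(values.size)
    order = np.lexsort((ids, -values))
    return np.sort(order[:k])


def select_roi(
    per_subject_maps: np.ndarray,
    mode: str,
    metric: str,
    hemisphere: str,
    roi_size: int = ROI_SIZE,
):
    """Top-``roi_size`` vertex selection from per-subject metric maps.

    ``per_subject_maps`` is (n_subjects, n_vertices).  In "common" mode the
    maps are averaged over the pooled sample (all subjects, both groups) and
    one :class:`ROISelection` is returned; in "individual" mode one selection
    per subject.  Ties break by (value desc, vertex id asc).
    """
    maps = np.atleast_2d(np.asarray(per_subject_maps, dtype=float))
    if maps.shape[1] < roi_size:
        raise ValueError(
            f"only {maps.shape[1]} vertices available, ROI needs {roi_size}"
        )
    if mode == "common":
        if maps.shape[0] < 2:
            raise ValueError("common mode requires at least 2 subjects")
        mean_map = maps.mean(axis=0)
        return ROISelection(
            mode=mode,
            metric=metric,
            vertex_ids=_top_k(mean_map, roi_size),
            hemisphere=hemisphere,
            provenance=f"pooled average of {maps.shape[0]} subjects",
            roi_size=roi_size,
        )
    if mode == "individual":
        return [
            ROISelection(
                mode=mode,
                metric=metric,
                vertex_ids=_top_k(maps[i], roi_size),
                hemisphere=hemisphere,
                provenance=f"subject index {i}",
                roi_size=roi_size,
            )
            for i in range(maps.shape[0])
        ]
    raise ValueError("mode must be 'common' or 'individual'")


def locate_activation_maximum(
    metric_map: np.ndarray,
    vertex_coords: np.ndarray,
    threshold: float = ITPC_EXCLUSION_THRESHOLD,
    metric: str = "itpc",
) -> ActivationMaximum:
    """Argmax vertex with its stored coordinates; excluded at or below threshold."""
    values = np.asarray(metric_map, dtype=float)
    if values.size == 0:
        raise ValueError("empty metric map")
    vid = int(np.argmax(values))               # ties -> lowest id
    value = float(values[vid])
    included = value > threshold
    return ActivationMaximum(
        vertex_id=vid,
        coords=np.asarray(vertex_coords)[vid].copy(),
        value=value,
        included=included,
        reason="" if included else f"{metric} {value:.3f} <= threshold {threshold}",
    )


def compare_assr_groups(
    scalars: pd.DataFrame,
    cohort: pd.DataFrame,
    metrics: tuple = ("z_itpc", "power_change"),
    residualize_age: bool = False,
) -> pd.DataFrame:
    """Group, hemisphere and age analyses of band-interval ASSR scalars.

    ``scalars`` is long-format with columns subject_id, group, hemisphere and
    one column per metric (contralateral responses).  Per hemisphere the NT
    and ASD distributions are compared with the Mann-Whitney U test (medians
    reported); per group the two hemispheres with the Wilcoxon matched-pairs
    test; and Spearman age correlations are computed per group x hemisphere,
    optionally after subtracting the linear age trend.
    """
    ages = cohort.set_index("subject_id")["age"]
    rows = []
    for metric in metrics:
        wide = scalars.pivot_table(
            index=["subject_id", "group"], columns="hemisphere", values=metric
        ).reset_index()
        incomplete = wide[wide[["left", "right"]].isna().any(axis=1)]
        if len(incomplete):
            logger.info(
                "compare_assr_groups: dropping %d subjects without both hemispheres",
                len(incomplete),
            )
            wide = wide.dropna(subset=["left", "right"])
        for hemi in ("left", "right"):
            nt = wide.loc[wide["group"] == "NT", hemi].to_numpy()
            asd = wide.loc[wide["group"] == "ASD", hemi].to_numpy()
            res = sfstats.mann_whitney_u(asd, nt)
            rows.append(
                dict(metric=metric, test="mann-whitney", hemisphere=hemi,
                     statistic=res.statistic, p=res.p_raw,
                     median_asd=res.extras["median_a"], median_nt=res.extras["median_b"],
                     n=f"{asd.size}/{nt.size}")
            )
        for group in ("NT", "ASD"):
            sub = wide[wide["group"] == group]
            try:
                res = sfstats.wilcoxon_signed_rank(
                    sub["right"].to_numpy() - sub["left"].to_numpy()
                )
                stat, p, z = res.statistic, res.p_raw, res.extras.get("z")
            except ValueError as exc:
                logger.info("wilcoxon undefined for %s/%s: %s", metric, group, exc)
                stat = p = z = float("nan")
            rows.append(
                dict(metric=metric, test="wilcoxon-right-vs-left", hemisphere="both",
                     group=group, statistic=stat, p=p, z=z, n=str(len(sub)))
            )
        for group in ("NT", "ASD"):
            sub = wide[wide["group"] == group]
            age = ages.loc[sub["subject_id"]].to_numpy()
            for hemi in ("left", "right"):
                v = sub[hemi].to_numpy()
                try:
                    res = sfstats.correlation(
                        age, v, method="spearman",
                        residualize_on=age if residualize_age else None,
                    )
                    stat, p, n = res.statistic, res.p_raw, res.n[0]
                except ValueError as exc:
                    logger.info(
                        "age correlation undefined for %s/%s/%s: %s",
                        metric, group, hemi, exc,
                    )
                    stat = p = float("nan")
                    n = len(sub)
                rows.append(
                    dict(metric=metric, test="spearman-age", hemisphere=hemi,
                         group=group, statistic=stat, p=p, n=str(n))
                )
    return pd.DataFrame(rows)


def pointwise_timecourse_test(
    series: dict,
    q: float = 0.05,
    expected_family: int | None = None,
) -> dict:
    """Two-sample rank test at every timepoint, FDR-pooled across all series.

    ``series`` maps a name to ``(groups, values, times)`` where ``values`` is
    (n_subjects, n_points) and ``groups`` labels each subject "NT"/"ASD".
    One Benjamini-Hochberg correction runs over the pooled family of all
    points of all series.  Returns per-series p-maps and significance masks.
    """
    all_p = []
    keys = []
    for name, (groups, values, times) in series.items():
        groups = np.asarray(groups)
        values = np.asarray(values, dtype=float)
        p = np.empty(values.shape[1])
        a = values[groups == "ASD"]
        b = values[groups == "NT"]
        for j in range(values.shape[1]):
            p[j] = sfstats.mann_whitney_u(a[:, j], b[:, j]).p_raw
        all_p.append(p)
        keys.append(name)
    family = np.concatenate(all_p)
    if expected_family is not None and family.size != expected_family:
        raise ValueError(
            f"pooled family has {family.size} values, expected {expected_family}"
        )
    reject, adj = sfstats.fdr_bh(family, q=q)
    out = {}
    offset = 0
    for name, p in zip(keys, all_p):
        sl = slice(offset, offset + p.size)
        out[name] = {
            "times": series[name][2],
            "p_raw": p,
            "p_adj": adj[sl],
            "mask": reject[sl],
        }
        offset += p.size
    out["family_size"] = family.size
    return out
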