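"""Aggregation of ROI results and paired comparisons.

Bound-percentage estimates are aggregated per image (the pairing unit: an
image's outer-ROI mean vs its inner-ROI mean), and compared with two-tailed
paired t-tests. The two-tailed p comes from the regularized incomplete
beta function, p = I_{df/(df+t^2)}(df/2, 1/2), the exact tail integral of
Student's t. No multiple-testing correction is applied, and that is
recorded in the output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .errors import EmptyResultError, InvalidInputError
from .metabolic import BoundFractionResult

logger = logging.getLogger(__name__)

__all__ = [
    "ComparisonResult",
    "results_to_frame",
    "aggregate",
    "paired_t_test",
    "run_standard_comparisons",
    "simulate_image_means",
    "report_text",
]


def simulate_image_means(
    n_images: int,
    mean_a: float,
    mean_b: float,
    sd_a: float,
    sd_b: float,
    shared_sd: float = 2.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw paired per-image region means for study-level simulations.

    Each image carries a shared random offset (acquisition and fixation
    conditions common to both regions of one section) plus independent
    residuals, scaled so the marginal between-image SDs equal ``sd_a`` and
    ``sd_b``. The shared component induces the within-image correlation
    that makes a paired comparison more powerful than an unpaired one;
    ``shared_sd=0`` gives independent draws.
    """
    if rng is None:
        rng = np.random.default_rng()
    if not 0 <= shared_sd <= min(sd_a, sd_b):
        raise InvalidInputError(
            "shared_sd must lie in [0, min(sd_a, sd_b)] to keep marginal SDs"
        )
    u = rng.normal(0.0, shared_sd, size=n_images)
    resid_a = np.sqrt(sd_a**2 - shared_sd**2)
    resid_b = np.sqrt(sd_b**2 - shared_sd**2)
    a = mean_a + u + rng.normal(0.0, resid_a, size=n_images)
    b = mean_b + u + rng.normal(0.0, resid_b, size=n_images)
    return a, b


@dataclass(frozen=True)
class ComparisonResult:
    """One paired comparison: summary statistics plus the paired t-test."""

    name: str
    n_pairs: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    sem_a: float
    sem_b: float
    t_stat: float
    df: int
    p_two_tailed: float
    degenerate: bool = False  # zero-variance differences with nonzero mean

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "n_pairs": self.n_pairs,
            "mean_a": self.mean_a,
            "mean_b": self.mean_b,
            "sd_a": self.sd_a,
            "sd_b": self.sd_b,
            "sem_a": self.sem_a,
            "sem_b": self.sem_b,
            "t_stat": self.t_stat,
            "df": self.df,
            "p_two_tailed": self.p_two_tailed,
            "degenerate": self.degenerate,
        }


def results_to_frame(
    results: list[BoundFractionResult], image_id: str | int = 0
) -> pd.DataFrame:
    """Flatten per-ROI results into the tabular form stats consumes."""
    rows = [
        {
            "image_id": image_id,
            "roi_id": r.roi_id,
            "zone": r.zone,
            "region": r.region,
            "side": r.side,
            "bound_pct": r.bound_pct,
            "n_pixels": r.n_pixels,
            "photons": r.total_photons,
            "g_com": r.com.g,
            "s_com": r.com.s,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def aggregate(table: pd.DataFrame, grouping: str = "image") -> pd.DataFrame:
    """Per-image (or per-eye) mean bound percentage by region and zone.

    Returns one row per group with columns ``outer``/``inner`` (region
    means over all zones) plus ``<zone>_overall`` and ``<zone>_outer``
    columns for each zone present. Groups with no valid ROI are dropped
    with a log entry.
    """
    if table.empty:
        raise EmptyResultError("ROI table is empty")
    key = {"image": "image_id", "eye": "eye_id"}.get(grouping)
    if key is None or key not in table.columns:
        raise InvalidInputError(
            f"grouping {grouping!r} needs a {key or grouping}_id column"
        )
    rows = []
    for gid, sub in table.groupby(key):
        sub = sub.dropna(subset=["bound_pct"])
        if sub.empty:
            logger.info("group %s has no valid ROI; dropped", gid)
            continue
        row: dict = {key: gid}
        for region in ("outer", "inner"):
            vals = sub.loc[sub["region"] == region, "bound_pct"]
            row[region] = float(vals.mean()) if len(vals) else np.nan
        for zone, zsub in sub.groupby("zone"):
            row[f"{zone}_overall"] = float(zsub["bound_pct"].mean())
            outer = zsub.loc[zsub["region"] == "outer", "bound_pct"]
            if len(outer):
                row[f"{zone}_outer"] = float(outer.mean())
        rows.append(row)
    if not rows:
        raise EmptyResultError("no group retained any valid ROI")
    return pd.DataFrame(rows).set_index(key)


def paired_t_test(values_a, values_b, name: str = "paired") -> ComparisonResult:
    """Two-tailed paired t-test on matched vectors.

    t = mean(d) / (sd(d)/sqrt(n)) on the differences d = a - b; the
    two-tailed p is the regularized incomplete beta tail of Student's t
    with n - 1 degrees of freedom. Zero-variance differences give p = 1
    when all differences are zero, else a degenerate flag with p = 0.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidInputError("paired vectors must be 1-D and equal length")
    n = a.size
    if n < 2:
        raise InvalidInputError("paired t-test needs n >= 2 pairs")
    d = a - b
    md = float(d.mean())
    sd_d = float(d.std(ddof=1))
    dof = n - 1
    degenerate = False
    if sd_d == 0.0:
        if md == 0.0:
            t_stat, p = 0.0, 1.0
        else:
            t_stat = np.inf if md > 0 else -np.inf
            p = 0.0
            degenerate = True
    else:
        t_stat = md / (sd_d / np.sqrt(n))
        p = float(special.betainc(dof / 2.0, 0.5, dof / (dof + t_stat**2)))
    return ComparisonResult(
        name=name,
        n_pairs=n,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        sem_a=float(a.std(ddof=1) / np.sqrt(n)),
        sem_b=float(b.std(ddof=1) / np.sqrt(n)),
        t_stat=float(t_stat),
        df=dof,
        p_two_tailed=p,
        degenerate=degenerate,
    )


_STANDARD = (
    ("outer_vs_inner", "outer", "inner"),
    ("far_periphery_vs_central_overall", "far_periphery_overall", "central_overall"),
    ("far_periphery_vs_central_outer", "far_periphery_outer", "central_outer"),
)


def run_standard_comparisons(aggregated: pd.DataFrame) -> list[ComparisonResult]:
    """The three standard paired comparisons on an aggregated table:
    outer vs inner retina, far periphery vs central (overall retina), and
    far periphery vs central (outer retina only); pairing within image.
    """
    out = []
    for name, col_a, col_b in _STANDARD:
        missing = [c for c in (col_a, col_b) if c not in aggregated.columns]
        if missing:
            raise InvalidInputError(
                f"comparison {name!r}: aggregated table lacks columns {missing}"
            )
        sub = aggregated[[col_a, col_b]].dropna()
        if len(sub) < 2:
            raise InvalidInputError(
                f"comparison {name!r}: fewer than 2 complete pairs"
            )
        out.append(paired_t_test(sub[col_a], sub[col_b], name=name))
    return out


def report_text(comparisons: list[ComparisonResult]) -> str:
    """Human-readable summary: mean +/- SD, n, p per comparison."""
    lines = ["Paired comparisons of bound NAD(P)H percentage",
             "(no multiple-testing correction applied)", ""]
    for c in comparisons:
        p_str = "< 0.0001" if 0 < c.p_two_tailed < 1e-4 else f"= {c.p_two_tailed:.4g}"
        lines.append(
            f"{c.name}: {c.mean_a:.1f} ± {c.sd_a:.1f} vs "
            f"{c.mean_b:.1f} ± {c.sd_b:.1f} (n = {c.n_pairs}, "
            f"t = {c.t_stat:.3f}, df = {c.df}, p {p_str})"
            + ("  [degenerate: zero-variance differences]" if c.degenerate else "")
        )
    return "\n".join(lines) + "\n"
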