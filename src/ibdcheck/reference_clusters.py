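"""Prediction ellipses for simulated relationship clusters and flagging.

Each simulated relationship yields a cloud of estimated (k0, k1) points.
Treating the cloud as approximately bivariate normal, a coverage-level
prediction ellipse is the set of points whose squared Mahalanobis distance
from the sample mean does not exceed the chi-square(2 df) quantile at the
coverage level.  A study pair is automatically flagged for a relationship
when it falls inside that relationship's ellipse and outside the ellipse for
unrelated pairs; the unrelated ellipse is Bonferroni-adjusted for the number
of study pairs, since the vast majority of pairs are unrelated.

The normal approximation is convenient but slightly light-tailed relative to
the actual estimator distribution, so a few genuinely unrelated pairs are
expected just outside their ellipse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

RIDGE = 1e-10


def bonferroni_adjust(coverage: float, n_pairs: int) -> float:
    """Adjusted coverage 1 - (1 - coverage) / n_pairs for the unrelated
    ellipse, so that roughly one unrelated study pair is expected outside."""
    if not 0.0 < coverage < 1.0:
        raise ValueError(f"coverage {coverage} outside (0, 1)")
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    return 1.0 - (1.0 - coverage) / n_pairs


@dataclass
class PredictionEllipse:
    """Bivariate-normal summary of a relationship cluster in (k0, k1)."""

    relationship: str
    mean: np.ndarray  # shape (2,)
    cov: np.ndarray  # shape (2, 2)
    coverage: float
    threshold: float  # chi-square(2 df) quantile at the coverage level
    n_sim: int

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).reshape(2)
        self.cov = np.asarray(self.cov, dtype=float).reshape(2, 2)

    def boundary(self, n_points: int = 200) -> np.ndarray:
        """(n_points, 2) polygon approximating the ellipse boundary."""
        theta = np.linspace(0, 2 * np.pi, n_points)
        circle = np.stack([np.cos(theta), np.sin(theta)])
        chol = np.linalg.cholesky(self.cov)
        return (self.mean[:, None] + np.sqrt(self.threshold) * (chol @ circle)).T


def fit_ellipse(
    points: np.ndarray, coverage: float = 0.95, relationship: str = ""
) -> PredictionEllipse:
    """Fit a prediction ellipse to simulated (k0, k1) points.

    Mean and covariance are the sample moments; a tiny ridge keeps the
    covariance invertible when a cluster is degenerate (e.g. duplicates with
    complete data collapse to a single point).
    """
    pts = np.asarray(points, dtype=float)
    pts = pts[np.isfinite(pts).all(axis=1)]
    if pts.shape[0] < 3:
        raise ValueError(f"need >= 3 finite points to fit an ellipse, got {pts.shape[0]}")
    mean = pts.mean(axis=0)
    cov = np.cov(pts.T, ddof=1)
    if np.linalg.det(cov) < RIDGE**2:
        cov = cov + RIDGE * np.eye(2)
    return PredictionEllipse(
        relationship=relationship,
        mean=mean,
        cov=cov,
        coverage=coverage,
        threshold=float(chi2.ppf(coverage, df=2)),
        n_sim=pts.shape[0],
    )


def mahalanobis_sq(points: np.ndarray, e: PredictionEllipse) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d = pts - e.mean
    sol = np.linalg.solve(e.cov, d.T)
    return np.einsum("ij,ji->i", d, sol)


def in_ellipse(point, e: PredictionEllipse) -> bool:
    """Closed-boundary membership: distance exactly at the threshold counts
    as inside."""
    point = np.asarray(point, dtype=float)
    if not np.isfinite(point).all():
        return False
    return bool(mahalanobis_sq(point, e)[0] <= e.threshold)


def fit_relationship_ellipses(
    sim_estimates: dict[str, pd.DataFrame],
    coverage: float,
    n_study_pairs: int,
) -> dict[str, PredictionEllipse]:
    """Fit one ellipse per simulated relationship.

    Only the unrelated ellipse gets the Bonferroni adjustment; the
    relationship ellipses keep the raw coverage so their extent reflects the
    cluster itself.
    """
    ellipses = {}
    for rel, df in sim_estimates.items():
        ok = df[df["status"] == "ok"]
        level = (
            bonferroni_adjust(coverage, n_study_pairs) if rel == "unrelated" else coverage
        )
        ellipses[rel] = fit_ellipse(
            ok[["k0", "k1"]].to_numpy(), coverage=level, relationship=rel
        )
    return ellipses


def flag_pairs(
    study: pd.DataFrame, ellipses: dict[str, PredictionEllipse]
) -> pd.DataFrame:
    """Automatically flag study pairs consistent with a close relationship.

    For every non-unrelated relationship, a pair is flagged when its (k0, k1)
    lies inside that relationship's ellipse and outside the (Bonferroni-
    adjusted) unrelated ellipse.  Rows are sorted by relationship then
    subject labels.  Columns: subject1, subject2, relationship, mode, k0, k1.
    """
    if "unrelated" not in ellipses:
        raise ValueError("flagging requires the unrelated ellipse")
    unrel = ellipses["unrelated"]
    ok = study[study["status"] == "ok"]
    pts = ok[["k0", "k1"]].to_numpy()
    rows = []
    if len(ok):
        outside_unrel = mahalanobis_sq(pts, unrel) > unrel.threshold
        for rel, e in ellipses.items():
            if rel == "unrelated":
                continue
            inside = mahalanobis_sq(pts, e) <= e.threshold
            for idx in np.flatnonzero(inside & outside_unrel):
                row = ok.iloc[idx]
                rows.append(
                    {
                        "subject1": row["subject1"],
                        "subject2": row["subject2"],
                        "relationship": rel,
                        "mode": "automatic",
                        "k0": row["k0"],
                        "k1": row["k1"],
                    }
                )
    df = pd.DataFrame(
        rows, columns=["subject1", "subject2", "relationship", "mode", "k0", "k1"]
    )
    return df.sort_values(
        ["relationship", "subject1", "subject2"], kind="mergesort"
    ).reset_index(drop=True)


def query_point(
    point, ellipses: dict[str, PredictionEllipse]
) -> dict[str, bool]:
    """Ellipse memberships of an arbitrary (k0, k1) coordinate — the
    scriptable replacement for flagging points by mouse click."""
    return {rel: in_ellipse(point, e) for rel, e in ellipses.items()}


def query_pair(
    study: pd.DataFrame, subject1: str, subject2: str,
    ellipses: dict[str, PredictionEllipse],
) -> pd.DataFrame:
    """Membership report for one named study pair (manual-equivalent flag)."""
    s1, s2 = sorted((subject1, subject2))
    row = study[(study["subject1"] == s1) & (study["subject2"] == s2)]
    if row.empty:
        raise KeyError(f"pair ({subject1}, {subject2}) not found among study pairs")
    k0, k1 = float(row.iloc[0]["k0"]), float(row.iloc[0]["k1"])
    memb = query_point((k0, k1), ellipses)
    return pd.DataFrame(
        [
            {
                "subject1": s1,
                "subject2": s2,
                "relationship": rel,
                "mode": "query",
                "k0": k0,
                "k1": k1,
                "inside": inside,
            }
            for rel, inside in memb.items()
        ]
    )
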