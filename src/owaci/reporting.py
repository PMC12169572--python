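"""Report writers and diagnostic plots.

CSV output is locale-independent (comma delimiter, '.' decimal point)
with floats at 10 significant digits, so identical runs produce
byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .pipeline import StudyResult
from .registry import DIMENSIONS

FLOAT_FMT = "%.10g"


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def write_study_reports(result: StudyResult, out_dir) -> list[Path]:
    """Write scores.csv, quality.csv, continents.csv, proportions.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    scores = result.scores_frame()
    _write(scores, out / "scores.csv")
    written.append(out / "scores.csv")

    qrows = [rep.summary() for rep in result.quality.values()]
    _write(pd.DataFrame(qrows), out / "quality.csv")
    written.append(out / "quality.csv")

    per_unit = result.units.reset_index(drop=True).copy()
    for level, rep in result.quality.items():
        per_unit[f"mahalanobis_sq_{level}"] = rep.distances
        per_unit[f"atypical_{level}"] = rep.flags
    _write(per_unit, out / "quality_per_unit.csv")
    written.append(out / "quality_per_unit.csv")

    _write(result.continent_summary, out / "continents.csv")
    written.append(out / "continents.csv")

    props = pd.concat([result.units.reset_index(drop=True),
                       result.proportions.reset_index(drop=True)], axis=1)
    _write(props, out / "proportions.csv")
    _write(result.continent_proportions, out / "continent_proportions.csv")
    written += [out / "proportions.csv", out / "continent_proportions.csv"]
    return written


def plot_score_histogram(scores, path, bins: int = 10) -> None:
    """Histogram of composite scores (discriminant-power diagnostic)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(np.asarray(scores, dtype=float), bins=bins,
            color="steelblue", edgecolor="white")
    ax.set_xlabel("composite indicator score")
    ax.set_ylabel("countries")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_correlation_scatter(scores, external, path) -> None:
    """Scores against the external validation variable."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(scores, external, s=24, color="steelblue", alpha=0.8)
    ax.set_xlabel("composite indicator score")
    ax.set_ylabel("external variable (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_outlier_ellipse(scores, external01, threshold, flags, path) -> None:
    """Bivariate scatter with the chi-square Mahalanobis ellipse."""
    X = np.column_stack([np.asarray(scores, float), np.asarray(external01, float)])
    mean = X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1)
    vals, vecs = np.linalg.eigh(cov)
    theta = np.linspace(0, 2 * np.pi, 200)
    circle = np.column_stack([np.cos(theta), np.sin(theta)])
    ellipse = mean + (circle * np.sqrt(vals * threshold)) @ vecs.T

    fig, ax = plt.subplots(figsize=(6, 4))
    flags = np.asarray(flags, bool)
    ax.scatter(X[~flags, 0], X[~flags, 1], s=24, color="steelblue", alpha=0.8)
    ax.scatter(X[flags, 0], X[flags, 1], s=36, color="crimson", label="atypical")
    ax.plot(ellipse[:, 0], ellipse[:, 1], color="darkorange")
    ax.set_xlabel("composite indicator score")
    ax.set_ylabel("external variable (rescaled)")
    if flags.any():
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
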