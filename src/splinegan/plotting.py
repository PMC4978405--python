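"""Basic fitted-spline visualization for a single gene."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .containers import TimecourseExperiment
from .design import build_design, natural_cubic_basis
from .diffexpr import fit_gene_models


def plot_gene_fit(
    experiment: TimecourseExperiment,
    gene: str,
    df: int = 3,
    path: str | Path | None = None,
):
    """Plot measured expression and the fitted spline curves for both groups.

    Blue: control model and points; red: treatment.  Vertical dashed lines
    mark the boundary and interior knots.  Returns the matplotlib figure.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = experiment.subset_genes([gene])
    design = build_design(sub, df=df)
    fits = fit_gene_models(sub, design)
    coef = fits.coefficients[0]
    m = design.m

    grid = np.linspace(design.knots.boundary[0], design.knots.boundary[1], 200)
    basis = natural_cubic_basis(grid, design.knots, design.t0)
    block = np.column_stack([np.ones_like(grid), basis])
    control_curve = block @ coef[: m + 1]
    treatment_curve = control_curve + block @ coef[m + 1:]

    fig, ax = plt.subplots(figsize=(6, 4))
    for group, color, curve in (
        ("control", "tab:blue", control_curve),
        ("treatment", "tab:red", treatment_curve),
    ):
        cols = sub.samples_in_group(group)
        ax.scatter(sub.annotations.loc[cols, "time"], sub.values.loc[gene, cols],
                   color=color, s=18, label=group)
        ax.plot(grid, curve, color=color)
    for knot in (design.knots.boundary[0], *design.knots.interior, design.knots.boundary[1]):
        ax.axvline(knot, color="grey", linestyle="--", linewidth=0.7)
    ax.set_xlabel("time [h]")
    ax.set_ylabel("log2 expression")
    ax.set_title(gene)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
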