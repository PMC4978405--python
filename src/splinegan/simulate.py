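"""Synthetic time-course generators mirroring the assumed statistical structure.

The default layout emulates a two-group (control vs treatment) design with
sampling at 0.25, 0.5, 1, 2, 4, 8 and 24 hours and two replicates per group
per time point.  Baseline profiles are random natural-spline curves on the
experiment's own knots, so the null model is exactly representable by the
fitted model and type-I-error checks carry no approximation bias.  Gene
noise variances follow a scaled inverse-chi-square prior (d0, s0^2), the
same hierarchy the moderated test assumes; defaults d0 = 4, s0^2 = 0.05 are
plausible log2-microarray-scale values.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ReferenceNetwork, TimecourseExperiment, canonical_edge
from .design import compute_knots, natural_cubic_basis

DEFAULT_TIMES = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 24.0)


@dataclass
class SimulationTruth:
    """Ground truth accompanying a simulated experiment."""

    de_genes: set[str] = field(default_factory=set)
    true_network: set[tuple[str, str]] | None = None
    params: dict = field(default_factory=dict)
    seed: int | None = None


def _gene_names(n_genes: int) -> list[str]:
    width = max(4, len(str(n_genes)))
    return [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]


def _layout(times: tuple[float, ...], reps: int) -> pd.DataFrame:
    """Sample sheet for a balanced two-group design."""
    rows = []
    for group in ("control", "treatment"):
        for t in times:
            for r in range(1, reps + 1):
                rows.append((f"{group}_t{t:g}_r{r}", group, float(t), str(r)))
    frame = pd.DataFrame(rows, columns=["sample", "group", "time", "replicate"])
    return frame.set_index("sample")


def _standardized_spline_columns(times_per_sample: np.ndarray, df: int) -> np.ndarray:
    """Natural-spline columns orthogonalized against the intercept, unit temporal variance.

    Random coefficients on these columns produce smooth curves whose
    amplitude is interpretable in expression-SD units, independent of the
    raw basis parameterization.
    """
    knots = compute_knots(times_per_sample, df)
    basis = natural_cubic_basis(times_per_sample, knots)
    x = np.column_stack([np.ones_like(times_per_sample), basis])
    q, _ = np.linalg.qr(x)
    return q[:, 1:] * np.sqrt(times_per_sample.size)


def _spline_curves(
    n_genes: int,
    times_per_sample: np.ndarray,
    df: int,
    rng: np.random.Generator,
    amplitude: float,
    intercept_loc: float = 7.0,
    intercept_scale: float = 1.0,
) -> np.ndarray:
    """Random smooth curves: intercept + spline profile with temporal SD ~ amplitude."""
    cols = _standardized_spline_columns(times_per_sample, df)
    intercepts = rng.normal(intercept_loc, intercept_scale, size=n_genes)
    coefs = rng.normal(0.0, amplitude / np.sqrt(cols.shape[1]), size=(n_genes, cols.shape[1]))
    return intercepts[:, None] + coefs @ cols.T


def simulate_de(
    n_genes: int = 2000,
    frac_de: float = 0.05,
    effect_size: float = 3.0,
    times: tuple[float, ...] = DEFAULT_TIMES,
    reps: int = 2,
    d0: float = 4.0,
    s02: float = 0.05,
    df: int = 3,
    baseline_amplitude: float = 1.0,
    seed: int | None = None,
) -> tuple[TimecourseExperiment, SimulationTruth]:
    """Two-group time course with a fraction of truly differential genes.

    Every gene receives a random smooth baseline shared by both groups plus
    Gaussian noise with variance drawn from the scaled inverse-chi-square
    prior (d0, s0^2).  A random subset of round(frac_de * n_genes) genes
    additionally receives a differential spline profile in the treatment
    group whose coefficients are scaled by ``effect_size`` in units of the
    gene's noise standard deviation.  With frac_de = 0 the output is
    byte-identical to the complete-null generator at the same seed.
    """
    if not 0.0 <= frac_de <= 1.0:
        raise ValueError("frac_de must lie in [0, 1]")
    if n_genes < 1:
        raise ValueError("need at least one gene")
    if d0 <= 0 or s02 < 0:
        raise ValueError("variance hyperparameters require d0 > 0 and s0^2 >= 0")
    ss = np.random.SeedSequence(seed)
    rng_base, rng_de = (np.random.default_rng(c) for c in ss.spawn(2))
    ann = _layout(times, reps)
    t_all = ann["time"].to_numpy(float)
    genes = _gene_names(n_genes)

    mu = _spline_curves(n_genes, t_all, df, rng_base, baseline_amplitude)
    sigma2 = d0 * s02 / rng_base.chisquare(d0, size=n_genes) if s02 > 0 else np.zeros(n_genes)
    sigma = np.sqrt(sigma2)
    noise = rng_base.standard_normal((n_genes, t_all.size)) * sigma[:, None]
    values = mu + noise

    n_de = int(np.floor(frac_de * n_genes + 0.5))
    de_idx = np.array([], dtype=int)
    if n_de > 0:
        de_idx = np.sort(rng_de.choice(n_genes, size=n_de, replace=False))
        # differential profile lives in the model span: constant offset plus
        # standardized spline columns; overall size = effect_size noise-SDs
        design_diff = np.column_stack(
            [np.ones_like(t_all), _standardized_spline_columns(t_all, df)]
        )
        scale = np.where(sigma[de_idx] > 0, sigma[de_idx], np.sqrt(s02) if s02 > 0 else 1.0)
        d_coef = (
            rng_de.standard_normal((n_de, design_diff.shape[1]))
            * effect_size * scale[:, None] / np.sqrt(design_diff.shape[1])
        )
        treated = (ann["group"] == "treatment").to_numpy()
        values[np.ix_(de_idx, np.flatnonzero(treated))] += d_coef @ design_diff[treated].T

    frame = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=ann.index)
    experiment = TimecourseExperiment(frame, ann)
    truth = SimulationTruth(
        de_genes={genes[i] for i in de_idx},
        true_network=None,
        params={
            "n_genes": n_genes, "frac_de": frac_de, "effect_size": effect_size,
            "times": tuple(times), "reps": reps, "d0": d0, "s02": s02, "df": df,
        },
        seed=seed,
    )
    return experiment, truth


def simulate_null(
    n_genes: int = 2000,
    times: tuple[float, ...] = DEFAULT_TIMES,
    reps: int = 2,
    d0: float = 4.0,
    s02: float = 0.05,
    df: int = 3,
    seed: int | None = None,
) -> TimecourseExperiment:
    """Complete-null two-group time course: both groups share every mean profile.

    Emulates a comparison between technical replicates, where no gene is
    truly differential; used to check the test's false-positive rate.
    """
    experiment, _ = simulate_de(
        n_genes=n_genes, frac_de=0.0, effect_size=0.0, times=times, reps=reps,
        d0=d0, s02=s02, df=df, seed=seed,
    )
    return experiment


def _clique_partition(n_edges: int) -> list[int]:
    """Greedy partition of an edge budget into disjoint cliques (K4, K3, K2)."""
    sizes: list[int] = []
    remaining = n_edges
    while remaining >= 6:
        sizes.append(4)
        remaining -= 6
    if remaining >= 3:
        sizes.append(3)
        remaining -= 3
    sizes.extend([2] * remaining)
    return sizes


def simulate_ggm_timecourse(
    n_genes: int = 30,
    n_edges: int = 40,
    pcor_strength: float = 0.4,
    times: tuple[float, ...] = DEFAULT_TIMES,
    reps: int = 2,
    df: int = 3,
    trend_sd: float = 0.1,
    seed: int | None = None,
) -> tuple[TimecourseExperiment, SimulationTruth]:
    """Time course whose treatment-group noise follows a sparse Gaussian graphical model.

    The precision matrix is Omega = I + s * A where A is the adjacency of a
    union of disjoint cliques covering exactly ``n_edges`` pairs, so every
    planted pair has partial correlation exactly -``pcor_strength`` and all
    other pairs exactly zero; positive definiteness holds for any strength
    below 1.  Small independent smooth time trends (SD ``trend_sd``, in
    noise-SD units) are superimposed per gene; keeping them small preserves
    the planted conditional-dependence structure.  Control samples are
    drawn independently from the same model.
    """
    if not 0.0 < pcor_strength < 1.0:
        raise ValueError("pcor_strength must lie in (0, 1)")
    if n_edges < 0:
        raise ValueError("n_edges cannot be negative")
    sizes = _clique_partition(n_edges)
    needed = sum(sizes)
    if needed > n_genes:
        raise ValueError(
            f"{n_edges} edges at strength {pcor_strength} need {needed} genes "
            f"in disjoint cliques, but only {n_genes} are available"
        )
    ss = np.random.SeedSequence(seed)
    rng_graph, rng_data = (np.random.default_rng(c) for c in ss.spawn(2))
    genes = _gene_names(n_genes)
    order = rng_graph.permutation(n_genes)

    omega = np.eye(n_genes)
    true_edges: set[tuple[str, str]] = set()
    pos = 0
    for size in sizes:
        members = order[pos:pos + size]
        pos += size
        for i_idx in range(size):
            for j_idx in range(i_idx + 1, size):
                a, b = members[i_idx], members[j_idx]
                omega[a, b] = omega[b, a] = pcor_strength
                true_edges.add(canonical_edge(genes[a], genes[b]))

    sigma = np.linalg.inv(omega)
    chol = np.linalg.cholesky(sigma)
    ann = _layout(times, reps)
    t_all = ann["time"].to_numpy(float)
    n_obs = t_all.size

    trend = _spline_curves(n_genes, t_all, df, rng_data, trend_sd) if trend_sd > 0 else (
        rng_data.normal(7.0, 1.0, size=n_genes)[:, None] * np.ones((1, n_obs))
    )
    noise = chol @ rng_data.standard_normal((n_genes, n_obs))
    values = trend + noise
    frame = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=ann.index)
    experiment = TimecourseExperiment(frame, ann)
    truth = SimulationTruth(
        de_genes=set(),
        true_network=true_edges,
        params={
            "n_genes": n_genes, "n_edges": n_edges, "pcor_strength": pcor_strength,
            "times": tuple(times), "reps": reps, "trend_sd": trend_sd,
            "clique_sizes": sizes,
        },
        seed=seed,
    )
    return experiment, truth


def make_toy_reference(
    true_network: set[tuple[str, str]],
    noise_edges: int = 0,
    nodes: list[str] | None = None,
    seed: int | None = None,
) -> ReferenceNetwork:
    """A reference interactome fixture: the true edges plus random extra pairs.

    ``noise_edges`` random pairs are drawn uniformly over the node pool;
    draws that duplicate an existing edge are silently absorbed, so the
    final edge count is |truth| + noise_edges - duplicates.
    """
    rng = np.random.default_rng(seed)
    edges = {canonical_edge(a, b) for a, b in true_network}
    pool = sorted(set(nodes) if nodes is not None else {n for e in edges for n in e})
    if noise_edges > 0 and len(pool) < 2:
        raise ValueError("need at least 2 nodes to draw noise edges")
    for _ in range(noise_edges):
        i, j = rng.choice(len(pool), size=2, replace=False)
        edges.add(canonical_edge(pool[i], pool[j]))
    return ReferenceNetwork(edges)
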