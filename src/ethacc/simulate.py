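"""Seeded generators of structured genotype panels and sparse-QTL traits.

The generator emulates the statistical structure the accuracy estimators
are sensitive to: a panel split into allele-frequency-diverged clusters
(Balding-Nichols model parameterized by Fst), optionally inbred dosage
coding (0/2 doubled haploids), local linkage disequilibrium induced by
Markov copying within marker blocks, and an additive sparse causal-QTL
phenotype with a target heritability.  It does not model recombination
maps, pedigrees or genotyping error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .panel import GenotypePanel, Phenotype

__all__ = ["SimConfig", "SimTruth", "simulate_genotypes",
           "simulate_phenotype", "hide_qtls", "structured_panel_scenario"]


@dataclass
class SimConfig:
    """Configuration for a synthetic structured panel.

    Parameters
    ----------
    fst : float
        Between-cluster allele-frequency divergence in (0, 1).
    inbred : bool
        Dosages in {0, 2} (fully homozygous lines) instead of Binomial(2).
    ld_block : int
        Length of marker blocks within which adjacent markers are copied
        from their left neighbour with probability ``ld_copy`` per sample,
        inducing local LD; 1 disables.
    ld_phase_flip : bool
        When True (default for multi-cluster panels) clusters after the
        first copy the *complementary* allele, so local LD has opposite
        phase across clusters — the breakdown of LD-phase persistence
        between diverged populations that makes marker-QTL associations
        learned in one cluster misleading in the other.
    cluster_sizes : tuple or None
        Explicit cluster sizes (must sum to n_samples); None splits evenly
        with the remainder in the first cluster.
    """

    n_samples: int = 200
    n_markers: int = 500
    n_clusters: int = 2
    fst: float = 0.1
    inbred: bool = True
    ld_block: int = 1
    ld_copy: float = 0.7
    ld_phase_flip: bool = True
    n_qtl: int = 10
    h2: float = 0.5
    seed: int = 0
    cluster_sizes: tuple | None = None

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if not 0 < self.fst < 1:
            raise ValueError("fst must lie in (0, 1)")
        if not 0 <= self.h2 <= 1:
            raise ValueError("h2 must lie in [0, 1]")
        if self.n_qtl > self.n_markers:
            raise ValueError("n_qtl cannot exceed n_markers")
        if self.ld_block < 1:
            raise ValueError("ld_block must be >= 1")
        if self.cluster_sizes is not None:
            if len(self.cluster_sizes) != self.n_clusters:
                raise ValueError("cluster_sizes length != n_clusters")
            if sum(self.cluster_sizes) != self.n_samples:
                raise ValueError("cluster_sizes must sum to n_samples")

    @property
    def sizes(self) -> np.ndarray:
        if self.cluster_sizes is not None:
            return np.asarray(self.cluster_sizes, dtype=int)
        base = self.n_samples // self.n_clusters
        sizes = np.full(self.n_clusters, base)
        sizes[0] += self.n_samples - base * self.n_clusters
        return sizes

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["cluster_sizes"] is not None:
            d["cluster_sizes"] = list(d["cluster_sizes"])
        return d


@dataclass
class SimTruth:
    """Ground truth of a simulated trait, for oracle tests."""

    qtl_indices: np.ndarray
    theta_true: np.ndarray
    genetic_values: np.ndarray
    realized_h2: float
    sigma2_e: float = np.nan
    cluster_labels: np.ndarray = field(default=None)  # type: ignore


def simulate_genotypes(config: SimConfig) -> GenotypePanel:
    """Simulate a clustered dosage panel under the Balding-Nichols model.

    Ancestral frequencies are Uniform(0.1, 0.9); each cluster's frequency
    is Beta(p(1-F)/F, (1-p)(1-F)/F) so that Corr across clusters reflects
    the requested Fst.  Dosages are Binomial(2, p_c) per sample, or
    2*Bernoulli(p_c) for inbred panels.  Within LD blocks each marker is
    copied from its left neighbour with probability ``ld_copy`` per
    sample.
    """
    rng = np.random.default_rng(config.seed)
    n, M = config.n_samples, config.n_markers
    F = config.fst
    p_anc = rng.uniform(0.1, 0.9, size=M)
    a = p_anc * (1 - F) / F
    b = (1 - p_anc) * (1 - F) / F
    sizes = config.sizes
    labels = np.repeat(np.arange(config.n_clusters), sizes)
    dosages = np.empty((n, M))
    row = 0
    for c in range(config.n_clusters):
        p_c = np.clip(rng.beta(a, b), 1e-6, 1 - 1e-6)
        nc = sizes[c]
        if config.inbred:
            dos = 2.0 * (rng.random((nc, M)) < p_c)
        else:
            dos = rng.binomial(2, p_c, size=(nc, M)).astype(float)
        dosages[row:row + nc] = dos
        row += nc
    if config.ld_block > 1:
        flip_rows = (config.ld_phase_flip & (labels > 0)
                     if config.n_clusters > 1
                     else np.zeros(n, dtype=bool))
        for j in range(1, M):
            if j % config.ld_block != 0:  # stay inside the block
                copy = rng.random(n) < config.ld_copy
                src = dosages[copy, j - 1]
                # opposite LD phase in later clusters: copy the complement
                fl = flip_rows[copy]
                dosages[copy, j] = np.where(fl, 2.0 - src, src)
    panel = GenotypePanel(
        dosages,
        [f"s{i:04d}" for i in range(n)],
        [f"m{j:05d}" for j in range(M)])
    panel.cluster_labels = labels  # type: ignore[attr-defined]
    return panel


def simulate_phenotype(panel: GenotypePanel, n_qtl: int, h2: float,
                       seed: int = 0, cluster_effect: float | None = None,
                       cluster_labels: np.ndarray | None = None
                       ) -> tuple[Phenotype, SimTruth]:
    """Draw a sparse additive trait y = 1 mu + Q theta + e on the panel.

    QTL positions are sampled without replacement among polymorphic
    markers, effects are standard normal, and the noise variance is set so
    that Var(Q theta) / (Var(Q theta) + sigma2_e) equals ``h2``.  With
    ``h2=0`` the effects are scaled to zero and the trait is pure
    unit-variance noise.  ``cluster_effect`` adds a mean shift of that
    size per cluster (a confounding scenario).
    """
    rng = np.random.default_rng(seed)
    M = panel.n_markers
    if n_qtl > M:
        raise ValueError("n_qtl cannot exceed the number of markers")
    poly = np.flatnonzero(panel.dosages.std(axis=0) > 0)
    for attempt in range(10):
        if poly.size >= n_qtl:
            qtl = np.sort(rng.choice(poly, size=n_qtl, replace=False))
        else:
            qtl = np.sort(rng.choice(M, size=n_qtl, replace=False))
        theta = rng.standard_normal(n_qtl)
        g = panel.dosages[:, qtl] @ theta
        var_g = g.var(ddof=0)
        if var_g > 0 or h2 == 0 or n_qtl == 0:
            break
        warnings.warn("all sampled QTLs monomorphic; resampling",
                      stacklevel=2)
    else:
        raise RuntimeError("could not sample polymorphic QTLs in 10 attempts")
    if h2 == 0 or n_qtl == 0:
        theta = np.zeros(n_qtl)
        g = np.zeros(panel.n_samples)
        s2e = 1.0
    elif h2 == 1:
        s2e = 0.0
    else:
        s2e = var_g * (1 - h2) / h2
    e = rng.standard_normal(panel.n_samples) * np.sqrt(s2e)
    y = g + e
    if cluster_effect is not None:
        if cluster_labels is None:
            cluster_labels = getattr(panel, "cluster_labels", None)
        if cluster_labels is None:
            raise ValueError("cluster_effect needs cluster labels")
        y = y + cluster_effect * cluster_labels
    var_y = y.var(ddof=0)
    realized = float(g.var(ddof=0) / var_y) if var_y > 0 else 0.0
    truth = SimTruth(qtl_indices=qtl, theta_true=theta, genetic_values=g,
                     realized_h2=realized, sigma2_e=s2e,
                     cluster_labels=cluster_labels)
    return Phenotype(y, trait_name="sim_trait"), truth


def hide_qtls(panel: GenotypePanel, truth: SimTruth
              ) -> tuple[GenotypePanel, SimTruth]:
    """Remove the causal columns from the observed marker panel.

    Returns a panel in which the QTLs are ungenotyped — prediction must
    then work entirely through marker-QTL linkage disequilibrium, as on a
    real array whose causal loci are not among the assayed markers.  The
    returned truth has ``qtl_indices`` set to -1 (no longer addressable).
    """
    keep = np.setdiff1d(np.arange(panel.n_markers), truth.qtl_indices)
    reduced = GenotypePanel(
        panel.dosages[:, keep],
        list(panel.sample_ids),
        [panel.marker_ids[j] for j in keep])
    labels = getattr(panel, "cluster_labels", None)
    if labels is not None:
        reduced.cluster_labels = labels  # type: ignore[attr-defined]
    new_truth = SimTruth(
        qtl_indices=np.full(truth.qtl_indices.size, -1),
        theta_true=truth.theta_true, genetic_values=truth.genetic_values,
        realized_h2=truth.realized_h2, sigma2_e=truth.sigma2_e,
        cluster_labels=truth.cluster_labels)
    return reduced, new_truth


def structured_panel_scenario(seed: int, n_samples: int = 200,
                              n_markers: int = 240,
                              cluster_sizes: tuple = (70, 130),
                              n_qtl: int = 8, h2: float = 0.5,
                              fst: float = 0.3, ld_block: int = 5,
                              cluster_shift: float = 2.0):
    """Canonical two-cluster study scenario for estimator comparisons.

    A diverged two-cluster inbred panel (unequal cluster sizes, strong
    divergence, local LD with cluster-specific phase), a sparse trait
    whose causal loci are *hidden* from the marker panel — prediction
    works through marker-QTL LD alone, as on a real array — and a
    between-cluster trait mean shift of ``cluster_shift`` genetic
    standard deviations (diverged breeding pools differ in trait means).
    This is the regime in which mixed-model estimators (CD/PEV)
    overestimate realized accuracy and training-set composition matters.

    Returns (panel, phenotype, truth); ``panel.cluster_labels`` marks the
    clusters, cluster 0 being the smaller one.
    """
    cfg = SimConfig(n_samples=n_samples, n_markers=n_markers, n_clusters=2,
                    fst=fst, inbred=True, ld_block=ld_block, n_qtl=n_qtl,
                    h2=h2, seed=seed, cluster_sizes=cluster_sizes)
    panel = simulate_genotypes(cfg)
    pheno, truth = simulate_phenotype(panel, n_qtl=n_qtl, h2=h2,
                                      seed=seed + 1_000_000)
    if cluster_shift:
        shift = cluster_shift * float(np.std(truth.genetic_values))
        pheno, truth = simulate_phenotype(panel, n_qtl=n_qtl, h2=h2,
                                          seed=seed + 1_000_000,
                                          cluster_effect=shift)
    reduced, hidden_truth = hide_qtls(panel, truth)
    return reduced, pheno, hidden_truth
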