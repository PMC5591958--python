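"""Synthetic datasets with the statistical structure the pipeline assumes.

The generator emulates a plasma-miRNA microarray study of endothelial
damage: ~1,205 features measured in 24 samples, of which a minority pass
the detection filter; a planted sparse Gaussian-graphical-model block of
co-expressed miRNAs containing a designated hub; a right-skewed
(lognormal) endothelial-microparticle (EMP) count per sample coupled to a
subset of features; and one genomic region (a 14q32-like cluster) whose
members are overrepresented inside the network block.  Ground truth —
planted precision matrix, edge set, EMP-associated features, implied
regression coefficients, hub and enriched region — is returned for
recovery scoring.

EMP coupling model.  A latent per-sample activity ``u ~ N(0,1)`` (think:
degree of endothelial damage) loads on each associated feature,
``x_j = lambda_j * u + sqrt(1 - lambda_j^2) * w_j``, where ``w`` carries
the planted network structure for network features and is independent
noise otherwise; ``log EMP = alpha + g*u + eps``.  Jointly Gaussian, this
is identical in distribution to log-EMP being linear in the associated
features plus independent noise (the implied regression coefficients are
stored in the truth object).  A shared factor is what makes many features
individually correlated with one scalar readout — with mutually
near-independent features that is impossible, however large the
coefficients.

All randomness flows from one seed through named substreams (structure,
expression, EMP, detection, regions, qPCR), so adding a later stage never
perturbs earlier draws and a fixed seed fixes every emitted byte.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .ioformats import (
    ExpressionMatrix,
    write_bed,
    write_expression,
    write_samples,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "make_precision_matrix",
    "sample_dataset",
    "sample_ct_table",
    "write_dataset",
    "read_truth",
]

_PD_MARGIN = 0.05  # smallest-eigenvalue floor for planted precision matrices


@dataclass
class SyntheticConfig:
    """Study-design knobs for the generator.

    Defaults mirror the emulated study: 1,205 assayed miRNAs in 24 plasma
    samples, 277 passing the 5% detection filter, 175 EMP-associated, a
    131-feature network block, and a 50-member genomic cluster with 19
    members inside the network block.
    """

    n_features: int = 1205
    n_samples: int = 24
    n_network: int = 131
    n_emp_associated: int = 175
    n_expressed: int = 277
    edge_density: float = 0.05
    partial_cor_range: tuple[float, float] = (0.3, 0.6)
    hub_degree: int = 8
    assoc_strength_range: tuple[float, float] = (0.5, 0.8)
    neg_assoc_fraction: float = 0.25
    emp_baseline: float = 7.0      # ln counts/ul; exp(7) ~ 1100 EMP/ul
    emp_factor_scale: float = 1.0
    emp_noise_sd: float = 0.5
    n_regions: int = 20
    enriched_region_size: int = 50
    enriched_overlap: int = 19
    detection_rate: float = 0.95
    exact_edge_count: bool = False
    group_labels: tuple[str, ...] = ("TAV", "BAV", "BAV_dil")
    seed: int = 0

    @classmethod
    def verification(cls, seed: int = 0) -> "SyntheticConfig":
        """Scaled configuration for end-to-end pipeline verification.

        The study-sized default (24 samples) is too small for shrinkage-GGM
        edge recovery at posterior probability 0.95 — as for any method, the
        per-edge evidence grows like ``|rho| * sqrt(n)``.  This preset keeps
        the planted structure qualitatively identical (network block with a
        hub, EMP-coupled subset, one enriched region) but uses a sample size
        at which recovery is statistically possible, so that a full run can
        be checked against the planted truth.  Sizes chosen by power
        analysis: see docs/methods.md.
        """
        return cls(
            n_features=200,
            n_samples=1000,
            n_network=60,
            n_emp_associated=80,
            n_expressed=120,
            edge_density=0.03,
            partial_cor_range=(0.25, 0.35),
            hub_degree=10,
            assoc_strength_range=(0.3, 0.5),
            n_regions=10,
            enriched_region_size=25,
            enriched_overlap=15,
            seed=seed,
        )

    @classmethod
    def scaled(cls, n_features: int, n_samples: int, seed: int = 0) -> "SyntheticConfig":
        """Default study proportions rescaled to a different platform size."""
        base = cls()
        f = n_features / base.n_features
        n_network = min(max(2, round(base.n_network * f)), n_features)
        n_expressed = min(max(n_network, round(base.n_expressed * f)), n_features)
        n_assoc = min(max(n_network, round(base.n_emp_associated * f)), n_expressed)
        region = max(2, round(base.enriched_region_size * f))
        overlap = max(1, min(round(base.enriched_overlap * f), n_network, region))
        region = min(region, overlap + (n_features - n_network))
        return cls(
            n_features=n_features,
            n_samples=n_samples,
            n_network=n_network,
            n_emp_associated=n_assoc,
            n_expressed=n_expressed,
            hub_degree=min(base.hub_degree, n_network - 1),
            n_regions=min(base.n_regions, max(2, n_features // 10)),
            enriched_region_size=region,
            enriched_overlap=overlap,
            seed=seed,
        )

    def validate(self) -> None:
        def err(name: str, msg: str) -> None:
            raise ValueError(f"SyntheticConfig.{name}: {msg}")

        if self.n_features < 1:
            err("n_features", "must be positive")
        if self.n_samples < 4:
            err("n_samples", "need at least 4 samples")
        if not 0 <= self.n_network <= self.n_features:
            err("n_network", "must lie in [0, n_features]")
        if not self.n_expressed <= self.n_features:
            err("n_expressed", "cannot exceed n_features")
        if self.n_emp_associated != 0 and not (
            self.n_network <= self.n_emp_associated <= self.n_expressed
        ):
            err("n_emp_associated",
                "need n_network <= n_emp_associated <= n_expressed (or exactly 0)")
        if not 0.0 <= self.edge_density < 1.0:
            err("edge_density", "must be a probability in [0, 1)")
        lo, hi = self.partial_cor_range
        if not (0.0 < lo <= hi < 1.0):
            err("partial_cor_range", "magnitudes must satisfy 0 < lo <= hi < 1")
        if self.hub_degree < 0 or (self.n_network and self.hub_degree > self.n_network - 1):
            err("hub_degree", "must be in [0, n_network - 1]")
        slo, shi = self.assoc_strength_range
        if not (0.0 <= slo <= shi < 1.0):
            err("assoc_strength_range", "loadings must satisfy 0 <= lo <= hi < 1")
        if not 0.0 <= self.neg_assoc_fraction <= 1.0:
            err("neg_assoc_fraction", "must be a probability")
        if self.emp_noise_sd < 0:
            err("emp_noise_sd", "must be non-negative")
        if self.n_regions < 1:
            err("n_regions", "need at least one region")
        if self.enriched_overlap > min(self.enriched_region_size, max(self.n_network, 0)):
            err("enriched_overlap",
                "cannot exceed min(enriched_region_size, n_network)")
        if self.enriched_region_size - self.enriched_overlap > self.n_features - self.n_network:
            err("enriched_region_size",
                "not enough non-network features for the cluster remainder")
        if not 0.0 <= self.detection_rate <= 1.0:
            err("detection_rate", "must be a probability")


@dataclass
class SyntheticTruth:
    """Planted ground truth, kept for recovery scoring."""

    network_features: list[str]
    precision_matrix: np.ndarray
    true_edges: list[tuple[str, str]]
    pcor_compression: float            # uniform scaling applied for PD, 1.0 = none
    emp_associated: list[str]
    emp_coefficients: dict[str, float]  # implied regression of log-EMP on features
    factor_loadings: dict[str, float]
    enriched_region: str
    enriched_members: list[str]
    hub_feature: str | None

    def true_edge_set(self) -> set[frozenset]:
        return {frozenset(e) for e in self.true_edges}

    def to_json(self, path: str) -> None:
        payload = {
            "network_features": self.network_features,
            "precision_matrix": np.asarray(self.precision_matrix).tolist(),
            "true_edges": [list(e) for e in self.true_edges],
            "pcor_compression": self.pcor_compression,
            "emp_associated": self.emp_associated,
            "emp_coefficients": self.emp_coefficients,
            "factor_loadings": self.factor_loadings,
            "enriched_region": self.enriched_region,
            "enriched_members": self.enriched_members,
            "hub_feature": self.hub_feature,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            network_features=d["network_features"],
            precision_matrix=np.asarray(d["precision_matrix"]),
            true_edges=[tuple(e) for e in d["true_edges"]],
            pcor_compression=d["pcor_compression"],
            emp_associated=d["emp_associated"],
            emp_coefficients=d["emp_coefficients"],
            factor_loadings=d["factor_loadings"],
            enriched_region=d["enriched_region"],
            enriched_members=d["enriched_members"],
            hub_feature=d["hub_feature"],
        )


read_truth = SyntheticTruth.from_json


# ---------------------------------------------------------------------------
# planted precision matrices
# ---------------------------------------------------------------------------

def make_precision_matrix(
    p: int,
    density: float,
    magnitude_range: tuple[float, float] = (0.3, 0.6),
    seed: int | np.random.Generator = 0,
    extra_edges: list[tuple[int, int]] | None = None,
    margin: float = _PD_MARGIN,
    exact_count: bool = False,
) -> np.ndarray:
    """Unit-diagonal precision matrix with an Erdos-Renyi edge pattern.

    Off-diagonal entries are minus the planted partial correlations, whose
    magnitudes are drawn from ``magnitude_range`` with random signs.  If
    the resulting matrix is not positive definite with the requested
    eigenvalue margin, every off-diagonal entry is scaled by one common
    factor ``gamma < 1`` chosen so that the smallest eigenvalue equals the
    margin — support and relative magnitudes are preserved exactly, and
    nothing changes when the planted matrix is already comfortably PD.
    """
    theta, gamma = _make_precision(
        p, density, magnitude_range, seed, extra_edges, margin, exact_count
    )
    return theta


def _make_precision(p, density, magnitude_range, seed, extra_edges=None,
                    margin=_PD_MARGIN, exact_count=False) -> tuple[np.ndarray, float]:
    if p < 1:
        raise ValueError("p must be >= 1")
    if not 0.0 <= density < 1.0:
        raise ValueError(f"density must be in [0, 1), got {density}")
    lo, hi = magnitude_range
    if not (0.0 < lo <= hi < 1.0):
        raise ValueError("magnitudes must satisfy 0 < lo <= hi < 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    iu = np.triu_indices(p, 1)
    if exact_count:
        # realize the nominal sparsity exactly: a binomial draw can halve
        # the planted signal mass by chance at benchmark sizes
        n_edges = int(round(density * iu[0].size))
        support = np.zeros(iu[0].size, dtype=bool)
        support[rng.choice(iu[0].size, size=n_edges, replace=False)] = True
    else:
        support = rng.random(iu[0].size) < density
    if extra_edges:
        pos = {(min(i, j), max(i, j)) for i, j in extra_edges}
        extra_mask = np.array([(i, j) in pos for i, j in zip(*iu)])
        support = support | extra_mask
    k = int(support.sum())
    r = np.zeros((p, p))
    values = rng.uniform(lo, hi, k) * rng.choice([-1.0, 1.0], k)
    r[iu[0][support], iu[1][support]] = values
    r += r.T

    theta = np.eye(p) - r
    if k:
        lmin = float(np.linalg.eigvalsh(theta)[0])
        gamma = 1.0
        if lmin < margin:
            gamma = (1.0 - margin) / (1.0 - lmin)
            theta = np.eye(p) - gamma * r
        lmin = float(np.linalg.eigvalsh(theta)[0])
        if lmin <= 0:
            raise AssertionError("precision matrix not positive definite after scaling")
    else:
        gamma = 1.0
    return theta, gamma


def _correlation_from_precision(theta: np.ndarray) -> np.ndarray:
    cov = np.linalg.inv(theta)
    d = 1.0 / np.sqrt(np.diag(cov))
    corr = cov * np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    return corr


# ---------------------------------------------------------------------------
# dataset sampling
# ---------------------------------------------------------------------------

def _feature_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"miR-SYN-{i + 1:0{width}d}" for i in range(n)]


def sample_dataset(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Draw one dataset: expression, sample table, locus annotation, truth."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("structure", "expression", "emp", "detection", "regions", "qpcr"),
            ss.spawn(6),
        )
    }

    nf, ns = config.n_features, config.n_samples
    nn, na, ne = config.n_network, config.n_emp_associated, config.n_expressed
    names = _feature_names(nf)
    network_ids = names[:nn]
    assoc_ids = names[:na]
    hub_id = names[0] if nn and config.hub_degree else None

    # --- planted structure ------------------------------------------------
    rng_struct = streams["structure"]
    if nn:
        extra = None
        if hub_id is not None:
            partners = 1 + rng_struct.choice(nn - 1, size=config.hub_degree, replace=False)
            extra = [(0, int(j)) for j in partners]
        theta, gamma = _make_precision(
            nn, config.edge_density, config.partial_cor_range, rng_struct, extra,
            exact_count=config.exact_edge_count,
        )
        corr_block = _correlation_from_precision(theta)
        chol = np.linalg.cholesky(corr_block)
        iu = np.triu_indices(nn, 1)
        edge_mask = np.abs(theta[iu]) > 1e-12
        true_edges = [
            (names[i], names[j]) for i, j in zip(iu[0][edge_mask], iu[1][edge_mask])
        ]
    else:
        theta = np.zeros((0, 0))
        gamma = 1.0
        chol = None
        true_edges = []

    # --- structural draws (w) and latent EMP activity (u) -----------------
    rng_expr = streams["expression"]
    w = rng_expr.standard_normal((ns, nf))
    if chol is not None:
        w[:, :nn] = w[:, :nn] @ chol.T

    rng_emp = streams["emp"]
    u = rng_emp.standard_normal(ns)
    eps = rng_emp.standard_normal(ns) * config.emp_noise_sd
    slo, shi = config.assoc_strength_range
    lam = rng_emp.uniform(slo, shi, na)
    neg = rng_emp.random(na) < config.neg_assoc_fraction
    lam[neg] *= -1.0

    z = w.copy()
    if na:
        z[:, :na] = lam * u[:, None] + np.sqrt(1.0 - lam**2) * w[:, :na]

    log_emp = config.emp_baseline + config.emp_factor_scale * u + eps
    emp = np.exp(log_emp)

    # implied regression coefficients of log-EMP on the associated features
    if na:
        cw = np.eye(na)
        if nn:
            cw[:nn, :nn] = corr_block
        s = np.sqrt(1.0 - lam**2)
        c_assoc = np.outer(lam, lam) + cw * np.outer(s, s)
        beta = config.emp_factor_scale * np.linalg.solve(c_assoc, lam)
        emp_coefficients = {names[j]: float(beta[j]) for j in range(na)}
        factor_loadings = {names[j]: float(lam[j]) for j in range(na)}
    else:
        emp_coefficients = {}
        factor_loadings = {}

    # --- log2-intensity scale ---------------------------------------------
    mu = rng_expr.uniform(6.0, 14.0, nf)
    sigma = rng_expr.uniform(0.8, 1.5, nf)
    values = (mu[:, None] + sigma[:, None] * z.T).round(12)  # features x samples

    # --- detection flags ---------------------------------------------------
    rng_det = streams["detection"]
    detected = rng_det.random((nf, ns)) < config.detection_rate
    detected[ne:, :] = False  # features forced below the detection filter

    expr = ExpressionMatrix(names, [f"S{i + 1:02d}" for i in range(ns)], values, detected)

    # --- sample table -------------------------------------------------------
    groups = [config.group_labels[i % len(config.group_labels)] for i in range(ns)]
    samples = pd.DataFrame(
        {
            "sample_id": expr.sample_ids,
            "group": groups,
            "emp_per_ul": emp.round(12),
        }
    )
    samples["log_emp"] = np.log(samples["emp_per_ul"])

    # --- genomic regions ----------------------------------------------------
    rng_reg = streams["regions"]
    region_of = np.empty(nf, dtype=object)
    enriched_label = "chr14q32-like"
    inside = [0] if hub_id is not None else []
    pool = [i for i in range(nn) if i not in inside]
    need = config.enriched_overlap - len(inside)
    if need > 0:
        inside += sorted(int(i) for i in rng_reg.choice(pool, size=need, replace=False))
    outside_pool = np.arange(nn, nf)
    n_out = config.enriched_region_size - len(inside)
    outside = sorted(
        int(i) for i in rng_reg.choice(outside_pool, size=n_out, replace=False)
    ) if n_out > 0 else []
    cluster = sorted(inside + outside)
    for i in cluster:
        region_of[i] = enriched_label
    rest = [i for i in range(nf) if region_of[i] is None]
    other_labels = [f"chr{(k % 22) + 1}-R{k + 1:02d}" for k in range(config.n_regions - 1)]
    if other_labels:
        assignment = rng_reg.integers(0, len(other_labels), size=len(rest))
        for i, a in zip(rest, assignment):
            region_of[i] = other_labels[a]
    else:
        for i in rest:
            region_of[i] = "chr1-R01"

    region_index: dict[str, int] = {}
    records = []
    for i, name in enumerate(names):
        region = region_of[i]
        chrom = region.split("-")[0].replace("q32", "") if region != enriched_label else "chr14"
        k = region_index.get(region, 0)
        region_index[region] = k + 1
        start = 100_000 * (zlib.crc32(region.encode()) % 100 + 1) + 200 * k
        records.append((name, chrom, start, start + 60, region))
    loci = pd.DataFrame(records, columns=["feature_id", "chrom", "start", "end", "region"])

    truth = SyntheticTruth(
        network_features=network_ids,
        precision_matrix=theta,
        true_edges=true_edges,
        pcor_compression=float(gamma),
        emp_associated=assoc_ids,
        emp_coefficients=emp_coefficients,
        factor_loadings=factor_loadings,
        enriched_region=enriched_label,
        enriched_members=[names[i] for i in cluster],
        hub_feature=hub_id,
    )
    return expr, samples, loci, truth


def sample_ct_table(
    expr: ExpressionMatrix,
    samples: pd.DataFrame,
    targets: list[str],
    seed: int = 0,
    reference_id: str = "U6",
    ct_noise_sd: float = 0.15,
) -> pd.DataFrame:
    """Synthesize a qPCR Ct table from expression values.

    Cycle thresholds move inversely with log2 expression (one cycle per
    doubling); the endogenous control sits at a constant Ct plus noise.
    """
    rng = np.random.default_rng(seed)
    index = {f: i for i, f in enumerate(expr.feature_ids)}
    missing = [t for t in targets if t not in index]
    if missing:
        raise KeyError(f"targets not in expression matrix: {missing}")
    group_of = dict(zip(samples["sample_id"], samples["group"]))
    rows = []
    for target in targets:
        x = expr.values[index[target]]
        base = 32.0 - (x - x.mean())
        for j, sid in enumerate(expr.sample_ids):
            rows.append(
                {
                    "sample_id": sid,
                    "target_id": target,
                    "reference_id": reference_id,
                    "ct_target": round(float(base[j] + rng.normal(0, ct_noise_sd)), 6),
                    "ct_reference": round(float(22.0 + rng.normal(0, ct_noise_sd)), 6),
                    "group": group_of[sid],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# serialization of a full dataset
# ---------------------------------------------------------------------------

def write_dataset(outdir: str, config: SyntheticConfig) -> dict[str, str]:
    """Sample a dataset and write every artifact; returns the path map."""
    import os

    os.makedirs(outdir, exist_ok=True)
    expr, samples, loci, truth = sample_dataset(config)
    paths = {
        "expression": os.path.join(outdir, "expression.csv"),
        "detection": os.path.join(outdir, "detection.csv"),
        "samples": os.path.join(outdir, "samples.tsv"),
        "loci": os.path.join(outdir, "loci.bed"),
        "truth": os.path.join(outdir, "truth.json"),
        "config": os.path.join(outdir, "config.json"),
    }
    write_expression(expr, paths["expression"], paths["detection"])
    write_samples(samples, paths["samples"])
    write_bed(loci, paths["loci"])
    truth.to_json(paths["truth"])
    cfg = asdict(config)
    cfg["partial_cor_range"] = list(config.partial_cor_range)
    cfg["assoc_strength_range"] = list(config.assoc_strength_range)
    cfg["group_labels"] = list(config.group_labels)
    with open(paths["config"], "w") as fh:
        json.dump(cfg, fh, indent=1, sort_keys=True)
    return paths
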