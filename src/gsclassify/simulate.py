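"""Synthetic genotype-phenotype datasets with additive + epistatic architecture.

Genotypes are biallelic markers with allele frequencies drawn in a configured
range; adjacent-marker linkage disequilibrium is induced by thresholding a
first-order autoregressive Gaussian copula. Phenotypes are the sum of
additive marker effects, pairwise (dosage-product) epistatic effects and
Gaussian noise, with the noise residualized and rescaled so the in-sample
genetic fraction of variance equals the configured heritability exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from scipy.stats import norm

from .io import MarkerMatrix, PhenotypeVector, write_marker_matrix, write_phenotype


@dataclass(frozen=True)
class SimConfig:
    n: int = 306
    p: int = 1717
    coding: Literal["01", "012"] = "01"
    maf_range: tuple[float, float] = (0.1, 0.5)
    ld_rho: float = 0.0
    n_qtl: int = 30
    epistasis_pairs: int = 5
    h2: float = 0.5
    seed: int = 0
    trait_name: str = "trait"
    environment: str = "SIM"

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError(f"ld_rho must be in [0, 1), got {self.ld_rho}")
        if self.n_qtl > self.p:
            raise ValueError("n_qtl cannot exceed p")
        if 2 * self.epistasis_pairs > self.n_qtl:
            raise ValueError("need 2 * epistasis_pairs <= n_qtl")
        if not 0.0 < self.h2 < 1.0:
            raise ValueError(f"h2 must be in (0, 1), got {self.h2}")
        if self.n < 2 or self.p < 1:
            raise ValueError("need n >= 2 and p >= 1")


@dataclass(frozen=True)
class SimTruth:
    qtl_indices: np.ndarray
    additive_effects: np.ndarray  # on the final phenotype scale
    epistasis_pairs: np.ndarray  # k x 2 indices into markers
    epistasis_effects: np.ndarray
    offset: float
    g: np.ndarray
    realized_h2: float

    def genetic_values(self, markers: MarkerMatrix) -> np.ndarray:
        """Recompute g from stored effects; must match self.g to 1e-10."""
        X = markers.values.astype(float)
        g = X[:, self.qtl_indices] @ self.additive_effects
        for (i, j), e in zip(self.epistasis_pairs, self.epistasis_effects):
            g = g + e * X[:, i] * X[:, j]
        return g + self.offset


def _latent_ar1(n: int, p: int, rho: float, rng: np.random.Generator) -> np.ndarray:
    Z = np.empty((n, p))
    Z[:, 0] = rng.standard_normal(n)
    if p > 1:
        eps = rng.standard_normal((n, p - 1))
        c = np.sqrt(1.0 - rho**2)
        for j in range(1, p):
            Z[:, j] = rho * Z[:, j - 1] + c * eps[:, j - 1]
    return Z


def simulate_genotypes(cfg: SimConfig) -> MarkerMatrix:
    """Draw an n x p marker matrix under the configured coding and LD."""
    rng = np.random.default_rng(cfg.seed)
    freqs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=cfg.p)
    thresh = norm.ppf(freqs)  # latent < thresh <=> allele present
    n_gametes = 1 if cfg.coding == "01" else 2
    dosage = np.zeros((cfg.n, cfg.p), dtype=np.int64)
    for _ in range(n_gametes):
        Z = _latent_ar1(cfg.n, cfg.p, cfg.ld_rho, rng)
        dosage += (Z < thresh).astype(np.int64)
    ids = [f"ind{i + 1:04d}" for i in range(cfg.n)]
    markers = [f"m{j + 1:05d}" for j in range(cfg.p)]
    return MarkerMatrix(ids, markers, dosage, coding=cfg.coding)


def simulate_phenotypes(
    X: MarkerMatrix, cfg: SimConfig, max_retries: int = 20
) -> tuple[PhenotypeVector, SimTruth]:
    """Additive + pairwise-epistatic genetic values plus exact-h2 noise.

    The first 2 * epistasis_pairs sampled QTL are paired for interactions.
    Noise is residualized against g and rescaled so Var(g)/Var(y) == h2
    in-sample to machine precision.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    V = X.values.astype(float)
    for attempt in range(max_retries):
        qtl = np.sort(rng.choice(cfg.p, size=cfg.n_qtl, replace=False))
        a = rng.standard_normal(cfg.n_qtl)
        pairs = qtl[: 2 * cfg.epistasis_pairs].reshape(-1, 2) if cfg.epistasis_pairs else np.empty((0, 2), dtype=np.int64)
        e = rng.standard_normal(cfg.epistasis_pairs)
        g_raw = V[:, qtl] @ a
        for (i, j), eff in zip(pairs, e):
            g_raw = g_raw + eff * V[:, i] * V[:, j]
        if g_raw.std() > 0:
            break
        warnings.warn("monomorphic QTL draw produced zero genetic variance; resampling", stacklevel=2)
    else:
        raise RuntimeError("could not draw QTL with non-zero genetic variance")

    # center and scale g to variance h2 (ddof=0, in-sample)
    scale = np.sqrt(cfg.h2) / g_raw.std()
    mean_raw = g_raw.mean()
    g = scale * (g_raw - mean_raw)

    eps = rng.standard_normal(cfg.n)
    eps = eps - eps.mean()
    # project out the component along g so Cov(g, eps) == 0 in-sample
    eps = eps - (eps @ g) / (g @ g) * g
    eps = eps * np.sqrt(1.0 - cfg.h2) / eps.std()
    y = g + eps

    truth = SimTruth(
        qtl_indices=qtl,
        additive_effects=a * scale,
        epistasis_pairs=pairs,
        epistasis_effects=e[: cfg.epistasis_pairs] * scale,
        offset=-scale * mean_raw,
        g=g,
        realized_h2=float(g.var() / y.var()),
    )
    pv = PhenotypeVector(list(X.individual_ids), y, cfg.trait_name, cfg.environment)
    return pv, truth


def make_fixture(cfg: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write markers.csv, phenotype.csv, truth.csv and a simconfig snapshot."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    X = simulate_genotypes(cfg)
    pv, truth = simulate_phenotypes(X, cfg)
    paths = {
        "markers": write_marker_matrix(X, out_dir / "markers.csv"),
        "phenotype": write_phenotype(pv, out_dir / "phenotype.csv"),
    }
    truth_path = out_dir / "truth.csv"
    with open(truth_path, "w") as fh:
        fh.write("kind,marker_1,marker_2,effect\n")
        fh.write(f"offset,,,{float(truth.offset)!r}\n")
        for idx, eff in zip(truth.qtl_indices, truth.additive_effects):
            fh.write(f"additive,{X.marker_ids[idx]},,{float(eff)!r}\n")
        for (i, j), eff in zip(truth.epistasis_pairs, truth.epistasis_effects):
            fh.write(f"epistatic,{X.marker_ids[i]},{X.marker_ids[j]},{float(eff)!r}\n")
    paths["truth"] = truth_path
    genetic_path = out_dir / "genetic_values.csv"
    with open(genetic_path, "w") as fh:
        fh.write("individual_id,g\n")
        for iid, gv in zip(X.individual_ids, truth.g):
            fh.write(f"{iid},{float(gv)!r}\n")
    paths["genetic_values"] = genetic_path
    cfg_path = out_dir / "simconfig.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(
            {
                "n": cfg.n, "p": cfg.p, "coding": cfg.coding,
                "maf_range": list(cfg.maf_range), "ld_rho": cfg.ld_rho,
                "n_qtl": cfg.n_qtl, "epistasis_pairs": cfg.epistasis_pairs,
                "h2": cfg.h2, "seed": cfg.seed,
                "realized_h2": truth.realized_h2,
                "trait_name": cfg.trait_name, "environment": cfg.environment,
            },
            fh,
        )
    paths["simconfig"] = cfg_path
    return paths
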