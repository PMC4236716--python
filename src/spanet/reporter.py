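"""Reporter transcription factors: where significant expression change concentrates.

Each gene's differential-expression p-value is mapped to a z-score by the
inverse normal transform z = Phi^-1(1 - p).  A transcription factor with n
scored targets receives the aggregate raw score sum(z)/sqrt(n), which is then
size-corrected against an empirical background — the mean and standard
deviation of the same aggregate over random gene sets of size n drawn from
all scored genes — and converted to an upper-tail normal p-value.  TFs with
p below the threshold (default 0.05, uncorrected, matching the published
procedure) are the reporter TFs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReporterRecord:
    tf: str
    n_targets_scored: int
    raw_z: float
    corrected_z: float
    p_value: float
    significant: bool


@dataclass(frozen=True)
class RegulatoryNetwork:
    """Directed, unweighted TF -> target edges (deduplicated)."""

    edges: frozenset  # of (tf, target) pairs

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "RegulatoryNetwork":
        return cls(frozenset((tf, tg) for tf, tg in edges))

    @property
    def tfs(self) -> frozenset:
        return frozenset(tf for tf, _ in self.edges)

    def targets(self, tf: str) -> frozenset:
        return frozenset(tg for t, tg in self.edges if t == tf)


def gene_z_scores(gene_pvalues: Mapping[str, float]) -> dict[str, float]:
    """z = Phi^-1(1 - p) per gene; p clipped to [1e-15, 1 - 1e-15] first.

    p-values must lie in (0, 1]; offenders raise a ValueError naming the gene.
    """
    out: dict[str, float] = {}
    for gene in sorted(gene_pvalues):
        p = gene_pvalues[gene]
        if not (0.0 < p <= 1.0):
            raise ValueError(f"gene {gene!r}: p-value {p!r} outside (0, 1]")
        clipped = min(max(p, 1e-15), 1.0 - 1e-15)
        out[gene] = float(stats.norm.isf(clipped))
    return out


def score_reporters(
    regnet: RegulatoryNetwork,
    gene_z: Mapping[str, float],
    background_samples: int = 10000,
    seed: int = 0,
    alpha: float = 0.05,
) -> list[ReporterRecord]:
    """Size-corrected aggregate z-scores for every TF with scored targets.

    Genes appearing in the regulatory network but absent from the z-score map
    are dropped from target sets and from the background pool.  TFs left with
    zero scored targets are skipped with a warning.  Deterministic for a
    fixed seed; records sorted by p-value, then TF id.
    """
    if background_samples < 1000:
        raise ValueError("background_samples must be >= 1000 for a stable background")
    rng = np.random.default_rng(seed)
    genes = sorted(gene_z)
    pool = np.array([gene_z[g] for g in genes])
    if pool.size == 0:
        raise ValueError("no scored genes")

    tf_targets: dict[str, list[str]] = {}
    for tf in sorted(regnet.tfs):
        scored = sorted(t for t in regnet.targets(tf) if t in gene_z)
        if not scored:
            logger.warning("TF %s skipped: no target with an expression p-value", tf)
            continue
        tf_targets[tf] = scored

    # empirical background per distinct target-set size
    backgrounds: dict[int, tuple[float, float]] = {}
    for n in sorted({len(v) for v in tf_targets.values()}):
        n_draw = min(n, pool.size)
        sums = np.empty(background_samples)
        for b in range(background_samples):
            sums[b] = pool[rng.choice(pool.size, size=n_draw, replace=False)].sum()
        raw = sums / np.sqrt(n_draw)
        backgrounds[n] = (float(raw.mean()), float(raw.std(ddof=1)))

    records = []
    for tf, targets in tf_targets.items():
        n = len(targets)
        raw = float(sum(gene_z[t] for t in targets) / np.sqrt(n))
        mu, sigma = backgrounds[n]
        # a background spread at the float rounding scale is no spread at all
        if sigma <= 1e-12 * max(1.0, abs(mu)):
            corrected = 0.0
        else:
            corrected = (raw - mu) / sigma
        p = float(stats.norm.sf(corrected))
        records.append(ReporterRecord(tf, n, raw, corrected, p, p < alpha))
    records.sort(key=lambda r: (r.p_value, r.tf))
    return records
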