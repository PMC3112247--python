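"""Cluster (individual-level) nonparametric bootstrap of fitted quantities.

Error indicators are correlated within an individual, so resampling must
keep each individual's complete locus set together: every replicate draws
individuals with replacement up to the original count, refits the model
and re-evaluates the quantity of interest (typically a population-averaged
rate).  Duplicated individuals receive fresh identities so that each copy
gets its own random intercept in the refit, the standard cluster
bootstrap.

Replicates that fail to converge ("warnings") are tracked: the primary SD
is computed across converged replicates only, and an upper-bound variant
counts warned replicates' estimates as zero.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Iterable

import numpy as np

from .audit import ComparisonRecord
from .glmm import FitResult, ModelSpec, build_design, fit


@dataclasses.dataclass
class BootstrapResult:
    """Bootstrap SD of one scalar quantity.

    ``sd`` ignores non-converged replicates; ``sd_warnings_as_zero``
    treats their estimates as 0 (an upper bound on the impact of
    non-convergence); ``unreliable`` is set when warnings dominate.
    """

    quantity: str
    estimates: np.ndarray            # per-replicate values (NaN if warned)
    converged: np.ndarray            # per-replicate convergence flags
    n_replicates: int
    seed: int

    @property
    def warning_fraction(self) -> float:
        return 1.0 - float(self.converged.mean())

    @property
    def sd(self) -> float:
        vals = self.estimates[self.converged]
        return float(np.std(vals, ddof=1)) if len(vals) >= 2 else float("nan")

    @property
    def sd_warnings_as_zero(self) -> float:
        vals = np.where(self.converged, self.estimates, 0.0)
        return float(np.std(vals, ddof=1))

    @property
    def unreliable(self) -> bool:
        return self.warning_fraction > 0.5


def resample_individuals(records: list[ComparisonRecord],
                         rng: np.random.Generator) -> list[ComparisonRecord]:
    """Draw individuals with replacement; copies get distinct identities."""
    by_ind: dict[str, list[ComparisonRecord]] = {}
    for r in records:
        by_ind.setdefault(r.individual_id, []).append(r)
    ids = sorted(by_ind)
    picks = rng.integers(0, len(ids), size=len(ids))
    out: list[ComparisonRecord] = []
    for copy_no, idx in enumerate(picks):
        for r in by_ind[ids[idx]]:
            out.append(dataclasses.replace(
                r, individual_id=f"{r.individual_id}#bs{copy_no:04d}"))
    return out


def bootstrap_sd(records: Iterable[ComparisonRecord], spec: ModelSpec,
                 quantity: Callable[[FitResult], float],
                 n_boot: int = 500, seed: int = 0,
                 center_year: int = 2001, order: int = 20,
                 quantity_name: str = "quantity") -> BootstrapResult:
    """Bootstrap SD of ``quantity(fit)`` under individual resampling.

    Each replicate rebuilds the design from scratch (zero-error levels are
    re-detected per replicate, mirroring how a fresh dataset would be
    analyzed), refits by maximum marginal likelihood, and evaluates the
    quantity.  A replicate whose fit is flagged non-converged — or whose
    design degenerates (e.g. a resample with no errors at all) — counts
    as a warning.
    """
    if n_boot < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    recs = list(records)
    rng = np.random.default_rng(seed)
    estimates = np.full(n_boot, np.nan)
    converged = np.zeros(n_boot, dtype=bool)
    for b in range(n_boot):
        sample = resample_individuals(recs, rng)
        try:
            data = build_design(sample, spec, center_year=center_year)
            res = fit(data, order=order, compute_se=False)
        except (ValueError, np.linalg.LinAlgError):
            continue
        if not res.converged:
            continue
        try:
            estimates[b] = float(quantity(res))
        except (KeyError, ValueError):
            continue
        converged[b] = True
    return BootstrapResult(quantity_name, estimates, converged, n_boot, seed)
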