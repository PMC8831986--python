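"""Candidate-gene selection from fitness and expression matrices.

Three filters applied in order, each restricted to the cell lines shared by
the two matrices:

1. expression — drop genes never expressed (TPM > ``min_tpm`` in fewer than
   ``min_lines`` cell lines);
2. dependency — keep genes whose strongest depletion is below a fitness
   cutoff (default -0.5), i.e. genes some line genuinely depends on;
3. variability — keep genes whose per-row MAD exceeds the population median
   MAD by more than one MAD of the MADs (robust high-variance selection).

All cutoffs are strict inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FilterParams",
    "FilterReport",
    "filter_expressed",
    "filter_dependent",
    "filter_variable",
    "select_candidate_genes",
]


@dataclass(frozen=True)
class FilterParams:
    min_tpm: float = 0.0
    min_lines: int = 1
    fitness_cutoff: float = -0.5
    mad_constant: float = 1.0  # multiplier on MAD-of-MADs in the variability rule


@dataclass
class FilterReport:
    """Counts surviving each filter, in application order."""

    n_input: int
    n_expressed: int
    n_dependent: int
    n_variable: int
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        chain = [self.n_input, self.n_expressed, self.n_dependent, self.n_variable]
        if any(b > a for a, b in zip(chain, chain[1:])):
            raise ValueError(f"filter counts must be non-increasing, got {chain}")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_expressed": self.n_expressed,
            "n_dependent": self.n_dependent,
            "n_variable": self.n_variable,
            "genes": list(self.genes),
        }


def filter_expressed(
    expr: pd.DataFrame, min_tpm: float = 0.0, min_lines: int = 1
) -> list[str]:
    """Genes with TPM > ``min_tpm`` in at least ``min_lines`` cell lines."""
    if expr.empty:
        raise ValueError("expression matrix is empty")
    if min_lines > expr.shape[1]:
        raise ValueError(
            f"min_lines={min_lines} exceeds number of cell lines ({expr.shape[1]})"
        )
    hits = (expr.to_numpy(dtype=float) > min_tpm).sum(axis=1)
    return sorted(expr.index[hits >= min_lines].astype(str))


def filter_dependent(
    fitness: pd.DataFrame, genes: list[str], fitness_cutoff: float = -0.5
) -> list[str]:
    """Genes whose minimum fitness score is strictly below ``fitness_cutoff``."""
    missing = [g for g in genes if g not in fitness.index]
    if missing:
        raise KeyError(f"genes absent from fitness matrix: {missing[:5]}")
    sub = fitness.loc[genes]
    keep = sub.to_numpy(dtype=float).min(axis=1) < fitness_cutoff
    return sorted(np.asarray(genes)[keep].tolist())


def row_mad(values: np.ndarray) -> np.ndarray:
    """Per-row median absolute deviation, unscaled (no consistency constant)."""
    med = np.median(values, axis=1, keepdims=True)
    return np.median(np.abs(values - med), axis=1)


def filter_variable(
    fitness: pd.DataFrame, genes: list[str], mad_constant: float = 1.0
) -> list[str]:
    """Genes with row MAD > median(MADs) + mad_constant * MAD(MADs), strict."""
    if len(genes) < 3:
        raise ValueError(f"need >= 3 genes for a population MAD, got {len(genes)}")
    if fitness.shape[1] < 2:
        raise ValueError("need >= 2 cell lines to measure variability")
    missing = [g for g in genes if g not in fitness.index]
    if missing:
        raise KeyError(f"genes absent from fitness matrix: {missing[:5]}")
    mads = row_mad(fitness.loc[genes].to_numpy(dtype=float))
    pop_median = np.median(mads)
    pop_mad = np.median(np.abs(mads - pop_median))
    threshold = pop_median + mad_constant * pop_mad
    return sorted(np.asarray(genes)[mads > threshold].tolist())


def select_candidate_genes(
    fitness: pd.DataFrame,
    expr: pd.DataFrame,
    params: FilterParams = FilterParams(),
) -> FilterReport:
    """Run the three filters in order on the shared cell lines."""
    shared = [c for c in fitness.columns if c in set(expr.columns)]
    if len(shared) < 2:
        raise ValueError(
            f"fitness and expression matrices share only {len(shared)} cell lines; need >= 2"
        )
    fitness = fitness[shared]
    expr = expr[shared]
    common_genes = sorted(set(fitness.index) & set(expr.index))

    expressed = filter_expressed(
        expr.loc[common_genes], min_tpm=params.min_tpm, min_lines=params.min_lines
    )
    dependent = filter_dependent(fitness, expressed, params.fitness_cutoff)
    if len(dependent) >= 3:
        variable = filter_variable(fitness, dependent, params.mad_constant)
    else:
        variable = []
    return FilterReport(
        n_input=len(common_genes),
        n_expressed=len(expressed),
        n_dependent=len(dependent),
        n_variable=len(variable),
        genes=variable,
    )
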