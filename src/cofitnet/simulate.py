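"""Synthetic gene-fitness datasets with planted co-functional modules.

The generator emulates the data regime of a pooled CRISPR knockout screen
across a panel of cell lines: genes grouped into functional modules share a
latent fitness profile over cell lines, essential genes are shifted strongly
negative, a fraction of genes is not expressed at all, and curated pair lists
and ontology annotations align (noisily) with the planted modules.  Every
output is a deterministic function of the seed, so downstream stages can be
tested end-to-end without external downloads.

Module members relate to the latent profile either linearly or through a
monotonicity-destroying transform ``g(z) = |z| - E|z|``, which has exactly
zero linear correlation with ``z`` under symmetry while remaining strongly
dependent.  Such pairs are invisible to Pearson correlation but carry high
mutual information — the kind of association the ML scorer is meant to
recover where correlation-ranking methods fail.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_dataset",
    "simulate_curated_studies",
    "simulate_annotations",
]

# mean of |Z| for Z ~ N(0,1); used to recentre the nonlinear transform
_ABS_NORMAL_MEAN = float(np.sqrt(2.0 / np.pi))

# fixed offsets carving per-stage substreams out of the global seed
_FITNESS_OFFSET = 0
_EXPRESSION_OFFSET = 10_000
_STUDY_OFFSET = 20_000
_ANNOTATION_OFFSET = 30_000


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the planted-module fitness simulation.

    Defaults describe the standard benchmark condition used throughout the
    test suite: 300 genes over 40 cell lines with 10 planted modules of
    8–12 genes each.
    """

    n_genes: int = 300
    n_cell_lines: int = 40
    n_modules: int = 10
    module_size_range: tuple[int, int] = (8, 12)
    within_module_noise_sd: float = 0.3
    background_sd: float = 0.5
    essential_depth_mean: float = -1.0
    nonlinear_fraction: float = 0.2
    unexpressed_fraction: float = 0.1
    signal_scale: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.module_size_range
        if not (1 <= lo <= hi):
            raise ValueError(
                f"module_size_range must satisfy 1 <= min <= max, got {self.module_size_range}"
            )
        if self.n_modules * hi > self.n_genes:
            raise ValueError(
                f"n_modules * max module size = {self.n_modules * hi} exceeds n_genes = {self.n_genes}"
            )
        for name in ("nonlinear_fraction", "unexpressed_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.within_module_noise_sd < 0 or self.background_sd < 0:
            raise ValueError("noise standard deviations must be nonnegative")
        if self.n_cell_lines < 2:
            raise ValueError(f"n_cell_lines must be >= 2, got {self.n_cell_lines}")
        if self.essential_depth_mean > 0:
            raise ValueError(
                f"essential_depth_mean is a depletion depth and must be <= 0, "
                f"got {self.essential_depth_mean}"
            )


@dataclass
class GroundTruth:
    """Planted structure of a simulated dataset.

    ``planted_edges`` are exactly the unordered within-module gene pairs.
    ``pair_relation`` marks a planted pair ``nonlinear`` when exactly one of
    its genes uses the |z| transform (two |z| genes correlate linearly with
    each other, so such pairs remain ``linear``).
    """

    module_assignment: dict[str, int]  # gene -> module id; background genes absent
    planted_edges: set[frozenset[str]]
    pair_relation: dict[frozenset[str], str]  # 'linear' | 'nonlinear'
    essential_genes: set[str]
    nonlinear_genes: set[str] = field(default_factory=set)

    def modules(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for g, m in self.module_assignment.items():
            out.setdefault(m, set()).add(g)
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "module_assignment": self.module_assignment,
            "planted_edges": sorted(sorted(e) for e in self.planted_edges),
            "pair_relation": {
                "|".join(sorted(e)): rel for e, rel in sorted(
                    self.pair_relation.items(), key=lambda kv: sorted(kv[0])
                )
            },
            "essential_genes": sorted(self.essential_genes),
            "nonlinear_genes": sorted(self.nonlinear_genes),
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            module_assignment={g: int(m) for g, m in payload["module_assignment"].items()},
            planted_edges={frozenset(e) for e in payload["planted_edges"]},
            pair_relation={
                frozenset(k.split("|")): v for k, v in payload["pair_relation"].items()
            },
            essential_genes=set(payload["essential_genes"]),
            nonlinear_genes=set(payload.get("nonlinear_genes", [])),
        )


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _cell_line_ids(n: int) -> list[str]:
    return [f"CL{i:03d}" for i in range(1, n + 1)]


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw a fitness matrix, an expression matrix and their ground truth.

    Fitness model: module ``m`` has a latent profile ``z_m`` over cell lines,
    i.i.d. standard normal.  A member gene's row is

        essential_depth_mean + signal_scale * g(z_m) + eps,
        eps ~ N(0, within_module_noise_sd),

    where ``g`` is the identity for linear members and ``|z| - E|z|`` for a
    ``nonlinear_fraction`` of members.  Background genes are i.i.d.
    ``N(0, background_sd)``.  Expression is nonnegative (log-normal TPM)
    except for an ``unexpressed_fraction`` of genes which are all-zero;
    unexpressed genes are never module members, so their fitness rows carry
    background noise only.

    Returns ``(fitness, expression, truth)`` with genes as DataFrame rows and
    cell lines as columns.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + _FITNESS_OFFSET)
    genes = _gene_ids(config.n_genes)
    lines = _cell_line_ids(config.n_cell_lines)
    n, m = config.n_genes, config.n_cell_lines

    # unexpressed genes first; modules are planted among expressed genes only
    n_unexpressed = int(round(config.unexpressed_fraction * n))
    unexpressed = set(rng.choice(n, size=n_unexpressed, replace=False).tolist())
    expressed_idx = [i for i in range(n) if i not in unexpressed]

    lo, hi = config.module_size_range
    sizes = rng.integers(lo, hi + 1, size=config.n_modules)
    member_idx = rng.choice(expressed_idx, size=int(sizes.sum()), replace=False)

    fitness = rng.normal(0.0, config.background_sd, size=(n, m))
    module_assignment: dict[str, int] = {}
    nonlinear_genes: set[str] = set()
    pos = 0
    for mod_id, size in enumerate(sizes, start=1):
        members = member_idx[pos : pos + size]
        pos += size
        z = rng.standard_normal(m)
        n_nonlin = int(round(config.nonlinear_fraction * size))
        nonlin_members = set(rng.choice(members, size=n_nonlin, replace=False).tolist())
        for gi in members:
            gene = genes[gi]
            module_assignment[gene] = mod_id
            profile = np.abs(z) - _ABS_NORMAL_MEAN if gi in nonlin_members else z
            if gi in nonlin_members:
                nonlinear_genes.add(gene)
            fitness[gi] = (
                config.essential_depth_mean
                + config.signal_scale * profile
                + rng.normal(0.0, config.within_module_noise_sd, size=m)
            )

    # expression: log-normal TPM, independent of fitness; unexpressed rows zero
    expr_rng = np.random.default_rng(config.seed + _EXPRESSION_OFFSET)
    expression = expr_rng.lognormal(mean=2.0, sigma=1.0, size=(n, m))
    for gi in unexpressed:
        expression[gi] = 0.0

    planted_edges: set[frozenset[str]] = set()
    pair_relation: dict[frozenset[str], str] = {}
    for members in GroundTruth(module_assignment, set(), {}, set()).modules().values():
        for a, b in itertools.combinations(sorted(members), 2):
            e = frozenset((a, b))
            planted_edges.add(e)
            n_nl = (a in nonlinear_genes) + (b in nonlinear_genes)
            pair_relation[e] = "nonlinear" if n_nl == 1 else "linear"

    truth = GroundTruth(
        module_assignment=module_assignment,
        planted_edges=planted_edges,
        pair_relation=pair_relation,
        essential_genes=set(module_assignment),
        nonlinear_genes=nonlinear_genes,
    )
    fitness_df = pd.DataFrame(fitness, index=genes, columns=lines)
    expression_df = pd.DataFrame(expression, index=genes, columns=lines)
    fitness_df.index.name = expression_df.index.name = "gene"
    return fitness_df, expression_df, truth


def simulate_curated_studies(
    truth: GroundTruth,
    n_studies: int = 3,
    coverage: float = 0.8,
    fpr: float = 0.001,
    seed: int = 0,
    gene_universe: list[str] | None = None,
) -> list[set[frozenset[str]]]:
    """Emulate independently curated co-functional pair lists.

    Each study reports each planted edge with probability ``coverage`` and
    additionally reports non-planted pairs at rate ``fpr`` (drawn from the
    pair universe over ``gene_universe``, default: all genes in the truth's
    module assignment plus planted-edge genes).
    """
    if n_studies < 1:
        raise ValueError(f"n_studies must be >= 1, got {n_studies}")
    if not (0.0 <= coverage <= 1.0 and 0.0 <= fpr <= 1.0):
        raise ValueError("coverage and fpr must lie in [0, 1]")
    rng = np.random.default_rng(seed + _STUDY_OFFSET)
    planted = sorted(truth.planted_edges, key=sorted)
    if gene_universe is None:
        gene_universe = sorted({g for e in truth.planted_edges for g in e})
    universe_pairs = [
        frozenset(p) for p in itertools.combinations(sorted(gene_universe), 2)
    ]
    non_planted = [p for p in universe_pairs if p not in truth.planted_edges]

    studies: list[set[frozenset[str]]] = []
    for _ in range(n_studies):
        keep = rng.random(len(planted)) < coverage
        study = {e for e, k in zip(planted, keep) if k}
        if non_planted and fpr > 0:
            false_mask = rng.random(len(non_planted)) < fpr
            study |= {e for e, k in zip(non_planted, false_mask) if k}
        studies.append(study)
    return studies


def simulate_annotations(
    truth: GroundTruth,
    n_noise_terms: int = 20,
    seed: int = 0,
    gene_universe: list[str] | None = None,
    noise_term_size_range: tuple[int, int] = (5, 15),
) -> tuple[dict[str, set[str]], pd.DataFrame]:
    """Build module-aligned ontology annotations.

    One leaf term per planted module annotates its members; ``n_noise_terms``
    extra terms annotate random gene subsets.  All terms are children of a
    single root, giving a two-level DAG.  Returns ``(annotations, ontology)``
    where annotations map gene -> term ids (root excluded) and the ontology
    is a two-column child/parent DataFrame.
    """
    rng = np.random.default_rng(seed + _ANNOTATION_OFFSET)
    if gene_universe is None:
        gene_universe = sorted(truth.module_assignment)
    annotations: dict[str, set[str]] = {g: set() for g in gene_universe}

    edges: list[tuple[str, str]] = []
    root = "T:ROOT"
    for mod_id, members in sorted(truth.modules().items()):
        term = f"T:MOD{mod_id:02d}"
        edges.append((term, root))
        for g in sorted(members):
            annotations.setdefault(g, set()).add(term)
    lo, hi = noise_term_size_range
    for i in range(1, n_noise_terms + 1):
        term = f"T:NOISE{i:02d}"
        edges.append((term, root))
        size = int(rng.integers(lo, min(hi, len(gene_universe)) + 1))
        for g in rng.choice(gene_universe, size=size, replace=False):
            annotations[str(g)].add(term)
    ontology = pd.DataFrame(edges, columns=["child", "parent"])
    return annotations, ontology


def write_dataset(
    outdir: str | Path,
    fitness: pd.DataFrame,
    expression: pd.DataFrame,
    truth: GroundTruth,
) -> None:
    """Write the simulated dataset as plain-text artifacts (TSV + JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # full precision so a read-back matrix reproduces computations exactly
    fitness.to_csv(outdir / "fitness.tsv", sep="\t", float_format="%.17g")
    expression.to_csv(outdir / "expression.tsv", sep="\t", float_format="%.17g")
    truth.to_json(outdir / "ground_truth.json")


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["module_size_range"] = list(d["module_size_range"])
    return d
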