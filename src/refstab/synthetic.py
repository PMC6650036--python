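"""Synthetic longitudinal Cq datasets with known ground truth.

The generator emulates the shape of a developmental RT-qPCR panel: G
experimental groups (timepoints), a handful of biological replicates per
group, ~10 candidate reference genes plus an optional strongly regulated
target gene, and technical replicates per well.  All noise is Gaussian on
the Cq (log2) scale, matching the error structure of qPCR readouts.

Per gene i, sample s in group g, replicate r:

    Cq = baseline_i + delta_ig + block_drift_{b(i),s} + eps_is + nu_isr

where ``delta_ig`` is the deterministic group-mean drift, ``block_drift`` is
a per-sample random drift shared by all genes of a correlation block (a
minimal model of co-regulation), ``eps`` is per-sample biological noise and
``nu`` is technical replicate noise.

Three ready-made specs cover the study conditions used throughout the test
suite: :func:`developmental_spec` (a realistic 10-gene developmental panel),
:func:`recovery_spec` (two designed-stable genes among six drifting ones)
and :func:`coregulated_spec` (a strongly co-regulated unstable pair that
fools pairwise-variation methods).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GeneSpec",
    "SyntheticSpec",
    "generate",
    "developmental_spec",
    "recovery_spec",
    "coregulated_spec",
]


@dataclass
class GeneSpec:
    """Ground-truth parameters of one simulated gene.

    baseline_cq : mean Cq in the first group (cycles).
    group_deltas : additive group-mean shift per group (cycles); all zeros
        means the gene is designed stable.
    noise_sd : SD of per-sample biological noise (cycles).
    block_id : optional label of a co-regulation block; genes sharing a
        label also share a per-sample random drift.
    is_target : target genes are simulated but excluded from the candidate
        reference panel.
    """

    name: str
    baseline_cq: float
    group_deltas: list[float]
    noise_sd: float
    block_id: str | None = None
    is_target: bool = False


@dataclass
class SyntheticSpec:
    """Full description of a simulated longitudinal qPCR study."""

    group_names: list[str]
    samples_per_group: list[int]
    genes: list[GeneSpec]
    block_sd: dict[str, float] = field(default_factory=dict)  # per block, cycles
    replicate_sd: float = 0.08
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.samples_per_group) != len(self.group_names):
            raise ValueError("samples_per_group must match group_names")
        if any(n < 1 for n in self.samples_per_group):
            raise ValueError("each group needs at least one sample")
        if self.replicate_sd < 0 or self.n_replicates < 1:
            raise ValueError("invalid replicate settings")
        for gene in self.genes:
            if len(gene.group_deltas) != len(self.group_names):
                raise ValueError(f"{gene.name}: group_deltas length != number of groups")
            if gene.noise_sd < 0:
                raise ValueError(f"{gene.name}: negative noise SD")
            if gene.block_id is not None and gene.block_id not in self.block_sd:
                raise ValueError(f"{gene.name}: block {gene.block_id!r} has no block_sd")

    # -- (de)serialisation for the CLI ------------------------------------
    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticSpec":
        raw = json.loads(Path(path).read_text())
        raw["genes"] = [GeneSpec(**g) for g in raw["genes"]]
        return cls(**raw)

    def stable_genes(self) -> list[str]:
        """Designed-stable candidates: zero drift, no block, low noise."""
        return [
            g.name
            for g in self.genes
            if not g.is_target
            and all(d == 0 for d in g.group_deltas)
            and g.block_id is None
        ]


def generate(spec: SyntheticSpec, seed: int | None = None) -> tuple[pd.DataFrame, dict]:
    """Simulate a raw technical-replicate Cq table from a spec.

    Returns the long-format table (sample, group, gene, cq — one row per
    replicate) and a ground-truth record with the per-cell true mean Cq and
    the designed-stable gene list.  Reproducible: the same spec and seed give
    an identical table.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    sample_ids: list[str] = []
    sample_groups: list[str] = []
    for gname, n in zip(spec.group_names, spec.samples_per_group):
        for i in range(n):
            sample_ids.append(f"{gname}_s{i + 1}")
            sample_groups.append(gname)
    n_samples = len(sample_ids)

    block_drift = {
        block: rng.normal(0.0, sd, size=n_samples) for block, sd in spec.block_sd.items()
    }
    group_of = dict(zip(sample_ids, sample_groups))
    group_pos = {g: i for i, g in enumerate(spec.group_names)}

    rows = []
    truth_cells = {}
    for gene in spec.genes:
        eps = rng.normal(0.0, gene.noise_sd, size=n_samples)
        drift = block_drift.get(gene.block_id, np.zeros(n_samples))
        for s_idx, sample in enumerate(sample_ids):
            g = group_of[sample]
            true_cq = (
                gene.baseline_cq
                + gene.group_deltas[group_pos[g]]
                + drift[s_idx]
                + eps[s_idx]
            )
            truth_cells[(sample, gene.name)] = float(true_cq)
            nu = rng.normal(0.0, spec.replicate_sd, size=spec.n_replicates)
            for r in range(spec.n_replicates):
                rows.append((sample, g, gene.name, true_cq + nu[r]))

    table = pd.DataFrame(rows, columns=["sample", "group", "gene", "cq"])
    truth = {
        "stable_genes": spec.stable_genes(),
        "target_genes": [g.name for g in spec.genes if g.is_target],
        "candidate_genes": [g.name for g in spec.genes if not g.is_target],
        "true_mean_cq": truth_cells,
        "group_names": list(spec.group_names),
    }
    return table, truth


# ---------------------------------------------------------------------------
# ready-made study conditions
# ---------------------------------------------------------------------------

def developmental_spec(seed: int = 0) -> SyntheticSpec:
    """A realistic developmental panel: 4 timepoints, 5-6 samples per group,
    10 candidate genes plus one strongly induced myelin-like target.

    Two genes are designed stable (flat, quiet), two share a strongly
    drifting co-regulation block (the classic glycolysis-style pair that a
    pairwise method mistakes for stable), and the rest drift moderately.
    Noise SDs of 0.2-0.6 cycles and drifts up to ~1.5 cycles put the CV range
    in the regime typical of developing neural tissue panels.
    """
    genes = [
        GeneSpec("RefA", 22.0, [0, 0, 0, 0], 0.30),  # designed stable
        GeneSpec("RefB", 20.0, [0, 0, 0, 0], 0.35),  # designed stable
        GeneSpec("ActB", 17.0, [0, 0.3, 0.3, 0.1], 0.30),
        GeneSpec("RibC", 21.0, [0, -0.3, -0.4, -0.2], 0.40),
        GeneSpec("ChapD", 22.5, [0, 0.5, 0.7, 0.5], 0.40),
        GeneSpec("RibE", 19.0, [0, -0.4, -0.6, -0.4], 0.45),
        GeneSpec("MitoF", 23.0, [0, 0.6, 1.0, 0.8], 0.45),
        GeneSpec("GlycoG", 21.0, [0, 0.5, 0.9, 0.7], 0.45, block_id="glyco"),
        GeneSpec("GlycoH", 19.5, [0, 1.0, 1.5, 0.9], 0.35, block_id="glyco"),
        GeneSpec("TbpI", 24.0, [0, 0.9, 1.4, 1.0], 0.40, block_id="glyco"),
        GeneSpec("MyelinT", 26.0, [0, -3.5, -4.5, -5.0], 0.40, is_target=True),
    ]
    return SyntheticSpec(
        group_names=["P5", "P10", "P15", "P23"],
        samples_per_group=[5, 6, 6, 6],
        genes=genes,
        block_sd={"glyco": 0.55},
        replicate_sd=0.08,
        n_replicates=3,
        seed=seed,
    )


def recovery_spec(seed: int = 0) -> SyntheticSpec:
    """Two designed-stable genes (no group effect, 0.1-cycle noise) hidden
    among six drifting genes; used for pair-recovery runs.

    The drifting genes vary clearly across groups while keeping their CV
    around or below the workflow's 50 % screen, so runs exercise
    NormFinder's pair selection on a (nearly) full panel rather than the
    exclusion step.
    """
    genes = [
        GeneSpec("Stable1", 21.0, [0, 0, 0, 0], 0.10),
        GeneSpec("Stable2", 22.0, [0, 0, 0, 0], 0.10),
        GeneSpec("Drift1", 20.0, [0, 0.40, 0.60, 0.35], 0.30),
        GeneSpec("Drift2", 23.0, [0, -0.35, -0.55, -0.40], 0.30),
        GeneSpec("Drift3", 19.0, [0, 0.50, 0.80, 0.60], 0.35),
        GeneSpec("Drift4", 24.0, [0, -0.45, -0.70, -0.50], 0.35),
        GeneSpec("Drift5", 21.5, [0, 0.35, 0.65, 0.85], 0.40),
        GeneSpec("Drift6", 22.5, [0, -0.30, -0.60, -0.80], 0.40),
    ]
    return SyntheticSpec(
        group_names=["P5", "P10", "P15", "P23"],
        samples_per_group=[6, 6, 6, 6],
        genes=genes,
        block_sd={},
        replicate_sd=0.08,
        n_replicates=3,
        seed=seed,
    )


def coregulated_spec(seed: int = 0) -> SyntheticSpec:
    """A pair sharing a large common per-sample drift plus small independent
    noise, among independent moderately noisy genes.

    Pairwise-variation methods score the co-regulated pair as the most
    stable because their mutual ratio barely moves, even though each gene
    swings strongly across samples; overall-variation methods (CV) put the
    same pair at the bottom.

    The reversal requires the rest of the panel to carry ordinary biological
    noise of its own: with panel size k, pair-to-partner difference SD D and
    partner-to-partner difference SD s, the pair tops the GeNorm ranking iff
    (k-4)·D < (k-3)·s − SD(pair ratio).  Here the shared drift (1.4 cycles)
    exceeds the independents' noise (0.75 cycles), so the pair is also the
    most variable gene set by CV.
    """
    genes = [
        GeneSpec("CoregA", 20.0, [0, 0, 0, 0], 0.08, block_id="co"),
        GeneSpec("CoregB", 22.0, [0, 0, 0, 0], 0.08, block_id="co"),
        GeneSpec("Indep1", 21.0, [0, 0, 0, 0], 0.75),
        GeneSpec("Indep2", 19.0, [0, 0, 0, 0], 0.75),
        GeneSpec("Indep3", 23.0, [0, 0, 0, 0], 0.75),
    ]
    return SyntheticSpec(
        group_names=["P5", "P10", "P15", "P23"],
        samples_per_group=[6, 6, 6, 6],
        genes=genes,
        block_sd={"co": 1.4},
        replicate_sd=0.05,
        n_replicates=3,
        seed=seed,
    )
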