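"""Synthetic pooled CRISPR-KO screens with known ground truth.

The generator lays genes contiguously along chromosomes (a fixed number of
guides per gene), draws plasmid abundances once from a log-normal, assigns
every gene a true fitness effect — 0 for most, a spread of negative effects
for a planted essential fraction — and superimposes contiguous *bias
regions*: runs of genes whose guides are additionally depleted by a shared
regional shift, emulating the gene-independent response to cutting in
copy-number-amplified DNA.  Treatment counts are negative-binomial around
``plasmid * 2**logFC`` so replicate overdispersion resembles real screens.

Every randomised quantity flows from a single seed; the same config and seed
reproduce the same screen bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .io import CountTable


@dataclasses.dataclass(frozen=True)
class BiasRegion:
    """A contiguous run of genes sharing a gene-independent depletion shift."""

    chrom_index: int
    start_gene: int  # chromosome-local gene offset
    n_genes: int
    shift: float
    cn: int = 8
    expressed: bool = False


def _default_bias_regions() -> tuple[BiasRegion, ...]:
    return (
        BiasRegion(chrom_index=0, start_gene=40, n_genes=30, shift=-2.0),
        BiasRegion(chrom_index=7, start_gene=60, n_genes=30, shift=-1.5),
        BiasRegion(chrom_index=14, start_gene=10, n_genes=30, shift=-2.5),
    )


@dataclasses.dataclass
class SimulationConfig:
    """Study conditions for a synthetic screen.

    Defaults emulate a genome-wide human library: ~5 guides per gene across
    thousands of genes and multiple chromosomes, three treatment replicates,
    ~10% of genes essential with per-gene effects spread around -3 logFC
    (real essentials span a wide range of depletion strengths), and three
    planted 30-gene bias regions labelled copy-number amplified and
    non-expressed.
    """

    n_genes: int = 2000
    guides_per_gene: int = 5
    n_chromosomes: int = 20
    replicates: int = 3
    plasmid_log_mean: float = math.log(500.0)
    plasmid_log_sd: float = 0.5
    essential_fraction: float = 0.10
    essential_shift: float = -3.0
    essential_shift_sd: float = 1.0
    bias_regions: Sequence[BiasRegion] = dataclasses.field(
        default_factory=_default_bias_regions
    )
    noise_sd: float = 0.3
    nb_dispersion: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.essential_fraction <= 1:
            raise ValueError("essential_fraction must be in [0, 1]")
        if self.n_genes % self.n_chromosomes:
            raise ValueError("n_genes must divide evenly across chromosomes")
        per_chrom = self.n_genes // self.n_chromosomes
        seen: list[tuple[int, int, int]] = []
        for r in self.bias_regions:
            if r.chrom_index >= self.n_chromosomes:
                raise ValueError(f"bias region on unknown chromosome {r.chrom_index}")
            if r.start_gene < 0 or r.start_gene + r.n_genes > per_chrom:
                raise ValueError("bias region exceeds chromosome bounds")
            for c, s, e in seen:
                if c == r.chrom_index and s < r.start_gene + r.n_genes and r.start_gene < e:
                    raise ValueError("bias regions overlap")
            seen.append((r.chrom_index, r.start_gene, r.start_gene + r.n_genes))


@dataclasses.dataclass
class GroundTruth:
    """Planted per-gene labels and segment boundaries."""

    genes: pd.DataFrame  # gene, chrom, essential, true_effect, in_bias, cn, expressed
    regions: pd.DataFrame  # chrom, start_guide, end_guide (global, inclusive), shift

    @property
    def essential_genes(self) -> frozenset[str]:
        return frozenset(self.genes.loc[self.genes["essential"], "gene"])

    @property
    def bias_genes(self) -> frozenset[str]:
        return frozenset(self.genes.loc[self.genes["in_bias"], "gene"])


def simulate_screen(
    config: SimulationConfig | None = None,
) -> tuple[pd.DataFrame, CountTable, GroundTruth]:
    """Generate (library annotation, raw counts, ground truth) for one screen."""
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    per_chrom = cfg.n_genes // cfg.n_chromosomes
    g = cfg.guides_per_gene
    n_guides = cfg.n_genes * g

    width = len(str(cfg.n_genes))
    gene_names = np.array([f"G{i:0{width}d}" for i in range(cfg.n_genes)])
    gene_chrom_idx = np.repeat(np.arange(cfg.n_chromosomes), per_chrom)
    chrom_names = np.array([str(c + 1) for c in range(cfg.n_chromosomes)])

    guide_gene_idx = np.repeat(np.arange(cfg.n_genes), g)
    local_guide = np.arange(n_guides) % (per_chrom * g)
    library = pd.DataFrame(
        {
            "sgRNA": [f"sg_{i:06d}" for i in range(n_guides)],
            "gene": gene_names[guide_gene_idx],
            "chrom": chrom_names[gene_chrom_idx[guide_gene_idx]],
            "start": 1 + local_guide * 1000,
        }
    )
    library["end"] = library["start"] + 19  # 20-bp protospacer

    # per-gene truth
    essential = np.zeros(cfg.n_genes, dtype=bool)
    n_ess = int(round(cfg.essential_fraction * cfg.n_genes))
    essential[rng.choice(cfg.n_genes, size=n_ess, replace=False)] = True
    true_effect = np.zeros(cfg.n_genes)
    true_effect[essential] = rng.normal(
        cfg.essential_shift, cfg.essential_shift_sd, size=n_ess
    )

    in_bias = np.zeros(cfg.n_genes, dtype=bool)
    cn = np.full(cfg.n_genes, 2)
    expressed = np.ones(cfg.n_genes, dtype=bool)
    bias_shift_per_gene = np.zeros(cfg.n_genes)
    region_rows = []
    for r in cfg.bias_regions:
        lo = r.chrom_index * per_chrom + r.start_gene
        hi = lo + r.n_genes
        in_bias[lo:hi] = True
        cn[lo:hi] = r.cn
        expressed[lo:hi] = r.expressed | essential[lo:hi]
        bias_shift_per_gene[lo:hi] = r.shift
        region_rows.append(
            {
                "chrom": chrom_names[r.chrom_index],
                "start_guide": lo * g,
                "end_guide": hi * g - 1,
                "shift": r.shift,
            }
        )

    truth = GroundTruth(
        genes=pd.DataFrame(
            {
                "gene": gene_names,
                "chrom": chrom_names[gene_chrom_idx],
                "essential": essential,
                "true_effect": true_effect,
                "in_bias": in_bias,
                "cn": cn,
                "expressed": expressed,
            }
        ),
        regions=pd.DataFrame(
            region_rows, columns=["chrom", "start_guide", "end_guide", "shift"]
        ),
    )

    # guide-level truth and counts
    true_logfc = (
        true_effect[guide_gene_idx]
        + bias_shift_per_gene[guide_gene_idx]
        + rng.normal(0.0, cfg.noise_sd, size=n_guides)
    )
    plasmid = np.maximum(
        1, np.round(rng.lognormal(cfg.plasmid_log_mean, cfg.plasmid_log_sd, n_guides))
    ).astype(np.int64)

    data = library[["sgRNA", "gene"]].copy()
    data["plasmid"] = plasmid
    treatment_cols = []
    for r in range(cfg.replicates):
        mu = plasmid * np.exp2(true_logfc)
        if cfg.nb_dispersion > 0:
            shape = 1.0 / cfg.nb_dispersion
            lam = rng.gamma(shape, mu / shape)
        else:
            lam = mu
        col = f"rep{r + 1}"
        data[col] = rng.poisson(lam).astype(np.int64)
        treatment_cols.append(col)

    counts = CountTable(
        data=data,
        plasmid_column="plasmid",
        treatment_columns=tuple(treatment_cols),
        normalised=False,
    )
    return library, counts, truth


def worked_fixture() -> tuple[pd.DataFrame, CountTable, GroundTruth]:
    """A 60-guide miniature screen with hand-checkable integer counts.

    20 genes x 3 guides on one chromosome; genes G01-G03 essential (true
    logFC -3), genes G09-G20 form a 12-gene bias region (shift -2), no
    noise.  Plasmid counts are 160 everywhere so the shifted treatments are
    exact integers (-3 -> 20, -2 -> 40); the two replicates are identical,
    making the count back-transformation exact.
    """
    n_genes, g = 20, 3
    gene_names = [f"G{i + 1:02d}" for i in range(n_genes)]
    library = pd.DataFrame(
        {
            "sgRNA": [f"sg{i:03d}" for i in range(n_genes * g)],
            "gene": np.repeat(gene_names, g),
            "chrom": "1",
            "start": 1 + np.arange(n_genes * g) * 1000,
        }
    )
    library["end"] = library["start"] + 19

    essential = np.array([i < 3 for i in range(n_genes)])
    in_bias = np.array([i >= 8 for i in range(n_genes)])
    true_effect = np.where(essential, -3.0, 0.0)
    shift = np.where(in_bias, -2.0, 0.0)
    gene_logfc = true_effect + shift
    guide_logfc = np.repeat(gene_logfc, g)

    plasmid = np.full(n_genes * g, 160, dtype=np.int64)
    treated = (plasmid * np.exp2(guide_logfc)).astype(np.int64)
    data = library[["sgRNA", "gene"]].copy()
    data["plasmid"] = plasmid
    data["rep1"] = treated
    data["rep2"] = treated
    counts = CountTable(
        data=data, plasmid_column="plasmid", treatment_columns=("rep1", "rep2")
    )
    truth = GroundTruth(
        genes=pd.DataFrame(
            {
                "gene": gene_names,
                "chrom": "1",
                "essential": essential,
                "true_effect": true_effect,
                "in_bias": in_bias,
                "cn": np.where(in_bias, 8, 2),
                "expressed": ~in_bias,
            }
        ),
        regions=pd.DataFrame(
            [{"chrom": "1", "start_guide": 8 * g, "end_guide": n_genes * g - 1, "shift": -2.0}]
        ),
    )
    return library, counts, truth
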