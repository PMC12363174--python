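"""Synthetic data with the statistical structure the analysis assumes.

This module generates every input the pipeline consumes — strain
phylogenies, binary resource-trait matrices, per-strain killing
coefficients, confrontation trajectories, amplicon count tables, CFU
tables, and annotated genomes with planted T6SS clusters — so the full
analysis is testable end to end without external data.

Confrontation model
-------------------
A focal attacker is mixed 50/50 with an n-strain community and spotted on
agar. Growth is logistic and killing is contact-dependent, proxied by the
attacker's frequency phi(t) in the spot. On a time grid of step ``delta``:

    N_i(t + d) = N_i(t) * exp[(r_i (1 - sum_j N_j(t) / K)
                               - k_i * phi(t) * [arm == WT]) * d]

with phi(t) the focal strain's share of total abundance. The focal strain
is immune to itself (k = 0) and the Δhcp control arm never experiences
killing. Replicate noise is lognormal on initial abundances and shared
between the two arms of a replicate pair, because the assay splits one
master mix into both arms — the WT/control contrast then isolates killing.

All stochastic operations take explicit integer seeds; there is no global
random state.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from dendropy.simulate import treesim
from skbio import TreeNode

from .community import ARM_DHCP, ARM_WT, CountTable
from .errors import NumericalFailure
from .phylo import read_newick
from .screen import SUBTYPES, T6SS_CORE_COGS, GenomeAnnotation, Gene

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "generate_tree",
    "evolve_binary_traits",
    "assign_killing_coefficients",
    "simulate_confrontation",
    "sample_sequencing_counts",
    "sample_cfu",
    "plant_t6ss_genomes",
    "synthetic_tssb_panel_records",
    "mutate_protein",
    "run_confrontation_experiment",
]

FOCAL = "focal"


def _default_growth_rates(n: int) -> np.ndarray:
    # competitor growth rates evenly spread over 0.3-0.9 per hour
    return np.linspace(0.3, 0.9, n)


def _default_killing(n: int) -> np.ndarray:
    # susceptibilities evenly spaced over 0-0.8 per hour per unit focal freq
    return np.linspace(0.0, 0.8, n)


@dataclass
class SimulationConfig:
    """Parameters of one confrontation experiment.

    ``n_strains`` counts the competitor strains; the focal attacker is
    added on top with mixture fraction ``focal_fraction`` (default 0.5,
    the 50/50 assay design). ``growth_rates`` (per hour) and
    ``killing_coeffs`` (per hour per unit focal frequency, >= 0) are per
    competitor; defaults are r in [0.3, 0.9] and k evenly spaced in
    [0, 0.8]. ``focal_growth_rate`` applies to the attacker.
    """

    n_strains: int = 10
    focal_fraction: float = 0.5
    growth_rates: np.ndarray | None = None
    killing_coeffs: np.ndarray | None = None
    focal_growth_rate: float = 0.6
    carrying_capacity: float = 1e9
    initial_total: float = 1e7
    delta: float = 0.02
    timepoints: tuple = (0.0, 6.0, 24.0)
    n_replicates: int = 4
    replicate_noise_sd: float = 0.2
    seq_depth: int = 50_000
    plating_efficiency: float = 1.0
    seed: int = 0
    frequency_dependent: bool = True
    strain_names: tuple | None = None

    def __post_init__(self):
        if not 0 < self.focal_fraction < 1:
            raise ValueError("focal_fraction must be in (0, 1)")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.seq_depth < 1:
            raise ValueError("seq_depth must be >= 1")
        if list(self.timepoints) != sorted(self.timepoints) or self.timepoints[0] != 0:
            raise ValueError("timepoints must be ascending and start at 0")
        if self.growth_rates is None:
            self.growth_rates = _default_growth_rates(self.n_strains)
        self.growth_rates = np.asarray(self.growth_rates, dtype=float)
        if self.killing_coeffs is None:
            self.killing_coeffs = _default_killing(self.n_strains)
        self.killing_coeffs = np.asarray(self.killing_coeffs, dtype=float)
        if (self.killing_coeffs < 0).any():
            raise ValueError("killing coefficients must be >= 0")
        if len(self.growth_rates) != self.n_strains:
            raise ValueError("growth_rates length != n_strains")
        if len(self.killing_coeffs) != self.n_strains:
            raise ValueError("killing_coeffs length != n_strains")
        if self.strain_names is None:
            width = max(2, len(str(self.n_strains)))
            self.strain_names = tuple(
                f"S{i + 1:0{width}d}" for i in range(self.n_strains)
            )
        if len(self.strain_names) != self.n_strains:
            raise ValueError("strain_names length != n_strains")

    @property
    def all_strains(self) -> tuple:
        """Focal strain first, then competitors."""
        return (FOCAL, *self.strain_names)

    def with_killing(self, k) -> "SimulationConfig":
        return replace(self, killing_coeffs=np.asarray(k, dtype=float))


@dataclass
class Trajectory:
    """Deterministic-dynamics abundances per strain/timepoint/arm/replicate.

    ``abundances`` has shape (n_arms, n_timepoints, n_replicates,
    n_strains) with the focal strain first along the strain axis.
    """

    abundances: np.ndarray
    arms: tuple
    timepoints: tuple
    strains: tuple

    def at(self, arm: str, timepoint: float) -> np.ndarray:
        """(n_replicates, n_strains) slice for one arm and timepoint."""
        return self.abundances[self.arms.index(arm),
                               self.timepoints.index(timepoint)]

    def to_frame(self) -> pd.DataFrame:
        """Long format: strain, timepoint_h, arm, replicate, abundance."""
        rows = []
        for ai, arm in enumerate(self.arms):
            for ti, t in enumerate(self.timepoints):
                for ri in range(self.abundances.shape[2]):
                    for si, strain in enumerate(self.strains):
                        rows.append((strain, t, arm, ri + 1,
                                     self.abundances[ai, ti, ri, si]))
        return pd.DataFrame(
            rows, columns=["strain", "timepoint_h", "arm", "replicate", "abundance"]
        )


def generate_tree(n_tips: int, birth_rate: float = 1.0, death_rate: float = 0.0,
                  seed: int = 0) -> TreeNode:
    """A random birth-death strain phylogeny with ``n_tips`` extant tips.

    Tips are relabelled S01..Sn deterministically; zero-length terminal
    edges (tips born at the stopping instant) are clamped to a small
    positive length so every branch length is strictly positive.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if not birth_rate > death_rate >= 0:
        raise ValueError("need birth_rate > death_rate >= 0")
    dtree = treesim.birth_death_tree(
        birth_rate=birth_rate, death_rate=death_rate,
        num_extant_tips=n_tips, rng=random.Random(seed),
    )
    depth = max(leaf.distance_from_root() for leaf in dtree.leaf_node_iter())
    floor = max(depth, 1.0) * 1e-6
    for edge in dtree.preorder_edge_iter():
        if edge.head_node is dtree.seed_node:
            edge.length = None  # root has no branch
        elif edge.length is None or edge.length < floor:
            edge.length = floor
    width = max(2, len(str(n_tips)))
    for i, leaf in enumerate(sorted(dtree.leaf_node_iter(),
                                    key=lambda l: l.taxon.label)):
        leaf.taxon.label = f"S{i + 1:0{width}d}"
    newick = dtree.as_string(schema="newick", suppress_rooting=True)
    return read_newick(newick)


def evolve_binary_traits(tree: TreeNode, n_traits: int = 150,
                         gain_rate: float = 0.3, loss_rate: float = 0.3,
                         root_prob: float = 0.5, seed: int = 0) -> pd.DataFrame:
    """Evolve presence/absence traits down the tree by a two-state Markov
    process (gain 0->1 at ``gain_rate``, loss 1->0 at ``loss_rate``).

    Returns a tips x traits binary DataFrame. With small rates,
    phylogenetically close tips share more traits in expectation —
    the phylogenetic signal the resource-overlap analysis assumes.
    """
    tips = list(tree.tips())
    if not tips:
        raise ValueError("tree has no tips")
    if n_traits < 1:
        raise ValueError("n_traits must be >= 1")
    if gain_rate < 0 or loss_rate < 0:
        raise ValueError("rates must be >= 0")
    rng = np.random.default_rng(seed)
    total = gain_rate + loss_rate

    states = {id(tree): (rng.random(n_traits) < root_prob).astype(np.int8)}
    result = {}
    for node in tree.preorder(include_self=False):
        parent_state = states[id(node.parent)]
        t = node.length or 0.0
        if total == 0 or t == 0:
            child_state = parent_state.copy()
        else:
            decay = np.exp(-total * t)
            p1 = gain_rate / total  # stationary probability of presence
            p_state1 = np.where(parent_state == 1,
                                p1 + (1 - p1) * decay,
                                p1 * (1 - decay))
            child_state = (rng.random(n_traits) < p_state1).astype(np.int8)
        states[id(node)] = child_state
        if node.is_tip():
            result[node.name] = child_state
    traits = pd.DataFrame.from_dict(result, orient="index")
    traits.columns = [f"trait_{j + 1:03d}" for j in range(n_traits)]
    traits.index.name = "strain"
    return traits.sort_index()


def assign_killing_coefficients(predictor, intercept: float, slope: float,
                                noise_sd: float = 0.0, seed: int = 0) -> np.ndarray:
    """Plant a linear susceptibility-vs-predictor relationship.

    ``k_i = max(0, intercept + slope * predictor_i + eps_i)`` with
    ``eps_i ~ Normal(0, noise_sd^2)``. The predictor is typically resource
    overlap with the focal strain (slope > 0 plants the
    competition-relatedness effect) or minus cophenetic distance.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    predictor = np.asarray(predictor, dtype=float)
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, noise_sd, size=predictor.shape) if noise_sd else 0.0
    return np.maximum(0.0, intercept + slope * predictor + eps)


def simulate_confrontation(cfg: SimulationConfig) -> Trajectory:
    """Run the two-arm confrontation dynamics on the delta time grid.

    Both arms of a replicate share the same initial-abundance noise draw;
    only the WT arm applies the killing term. Raises
    :class:`NumericalFailure` if the state leaves the finite range.
    """
    n = cfg.n_strains
    r = np.concatenate([[cfg.focal_growth_rate], cfg.growth_rates])
    k_wt = np.concatenate([[0.0], cfg.killing_coeffs])  # focal immune to itself
    k_by_arm = {ARM_WT: k_wt, ARM_DHCP: np.zeros(n + 1)}

    rng = np.random.default_rng(cfg.seed)
    base = np.empty(n + 1)
    base[0] = cfg.focal_fraction * cfg.initial_total
    base[1:] = (1 - cfg.focal_fraction) * cfg.initial_total / n
    # one lognormal draw per replicate pair, shared across arms
    noise = np.exp(rng.normal(0.0, cfg.replicate_noise_sd,
                              size=(cfg.n_replicates, n + 1)))
    initial = base[None, :] * noise

    n_steps = int(round(cfg.timepoints[-1] / cfg.delta))
    record_steps = {int(round(t / cfg.delta)): ti
                    for ti, t in enumerate(cfg.timepoints)}

    arms = (ARM_WT, ARM_DHCP)
    out = np.empty((2, len(cfg.timepoints), cfg.n_replicates, n + 1))
    for ai, arm in enumerate(arms):
        k = k_by_arm[arm]
        state = initial.copy()  # (replicates, strains)
        if 0 in record_steps:
            out[ai, record_steps[0]] = state
        for step in range(1, n_steps + 1):
            total = state.sum(axis=1, keepdims=True)
            if cfg.frequency_dependent:
                with np.errstate(invalid="ignore"):
                    phi = np.where(total > 0, state[:, :1] / total, 0.0)
            else:
                phi = state[:, :1] / cfg.carrying_capacity
            growth = r[None, :] * (1.0 - total / cfg.carrying_capacity)
            state = state * np.exp((growth - k[None, :] * phi) * cfg.delta)
            if not np.isfinite(state).all():
                raise NumericalFailure(
                    f"non-finite abundance at step {step} (t={step * cfg.delta:.2f} h, "
                    f"arm={arm}); reduce delta or growth rates"
                )
            if step in record_steps:
                out[ai, record_steps[step]] = state
    return Trajectory(out, arms, tuple(cfg.timepoints), cfg.all_strains)


def sample_sequencing_counts(traj: Trajectory, depth: int, seed: int = 0) -> CountTable:
    """Multinomial amplicon reads per (timepoint, arm, replicate) sample.

    One draw of exactly ``depth`` reads per sample with probabilities
    proportional to abundances; emulates gyrB metabarcoding of the spot.
    The random stream is keyed by (seed, timepoint, replicate) but not by
    arm, so the two arms of a replicate pair with identical abundances
    (no killing) receive identical counts — the paired-design analogue of
    splitting one master mix.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rows, meta_rows, idx = [], [], []
    n_reps = traj.abundances.shape[2]
    for ai, arm in enumerate(traj.arms):
        for ti, t in enumerate(traj.timepoints):
            for ri in range(n_reps):
                rng = np.random.default_rng((seed, ti, ri))
                abund = traj.abundances[ai, ti, ri]
                total = abund.sum()
                if total <= 0:
                    raise ValueError(
                        f"all-zero abundances (arm={arm}, t={t}, rep={ri + 1})"
                    )
                counts = rng.multinomial(depth, abund / total)
                sample = f"{arm}_t{t:g}_r{ri + 1}"
                idx.append(sample)
                rows.append(counts)
                meta_rows.append({"arm": arm, "timepoint_h": t, "replicate": ri + 1})
    counts = pd.DataFrame(rows, index=idx, columns=list(traj.strains))
    meta = pd.DataFrame(meta_rows, index=idx)
    counts.index.name = meta.index.name = "sample"
    return CountTable(counts, meta)


def sample_cfu(traj: Trajectory, plating_efficiency: float = 1.0,
               seed: int = 0) -> pd.DataFrame:
    """Poisson CFU counts with mean ``N_i * plating_efficiency``.

    Long-format DataFrame (strain, timepoint_h, arm, replicate, cfu).
    """
    if not 0 < plating_efficiency <= 1:
        raise ValueError("plating_efficiency must be in (0, 1]")
    rng = np.random.default_rng(seed)
    frame = traj.to_frame()
    frame["cfu"] = rng.poisson(frame["abundance"].to_numpy() * plating_efficiency)
    return frame.drop(columns="abundance")


def _random_protein(rng: np.random.Generator, length: int) -> str:
    aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    return "".join(rng.choice(aa, size=length))


def mutate_protein(seq: str, fraction: float, rng: np.random.Generator) -> str:
    """Substitute a given fraction of positions with random residues."""
    aa = "ACDEFGHIKLMNPQRSTVWY"
    chars = list(seq)
    n_mut = int(round(fraction * len(chars)))
    for pos in rng.choice(len(chars), size=n_mut, replace=False):
        chars[pos] = aa[rng.integers(len(aa))]
    return "".join(chars)


def synthetic_tssb_panel_records(seed: int = 42, length: int = 168,
                                 n_per_subtype: int = 2,
                                 divergence: float = 0.06) -> list[tuple[str, str, str]]:
    """Synthetic TssB reference panel: (record id, subtype, sequence).

    One random ancestral sheath-protein sequence per subtype, each
    represented by ``n_per_subtype`` descendants at the given within-
    subtype divergence. A deterministic stand-in for a curated TssB
    reference set; distinct subtypes are unrelated random sequences.
    """
    rng = np.random.default_rng(seed)
    records = []
    for subtype in SUBTYPES:
        ancestor = _random_protein(rng, length)
        for j in range(n_per_subtype):
            seq = mutate_protein(ancestor, divergence, rng)
            records.append((f"tssb_{subtype}_{j + 1}", subtype, seq))
    return records


_DECOY_COGS = tuple(f"COG{1000 + 17 * i}" for i in range(40))


def plant_t6ss_genomes(n_genomes: int, clusters_per_genome, cog_completeness,
                       decoy_gene_count: int = 60, seed: int = 0,
                       min_core_cogs: int = 8,
                       tssb_subtypes=None) -> tuple[list[GenomeAnnotation], pd.DataFrame]:
    """Annotated genomes with planted T6SS clusters plus a truth table.

    ``clusters_per_genome``: int or per-genome sequence of cluster counts.
    ``cog_completeness``: int (1..10) or nested per-cluster sizes — the
    number of distinct core COGs each planted cluster carries. Each cluster
    is placed on its own contig (draft-genome style) as a contiguous run
    interleaved with at most 2 decoy genes; ``decoy_gene_count`` random
    non-T6SS genes pad a separate background contig. The truth table
    records each planted cluster and whether it meets ``min_core_cogs``
    (column ``callable``). Optional ``tssb_subtypes`` (flat list, cycled)
    labels planted clusters with a subtype recorded in the truth table.
    """
    rng = np.random.default_rng(seed)
    core = sorted(T6SS_CORE_COGS)

    def per_genome(value, i):
        if np.isscalar(value):
            return value
        return value[i]

    genomes, truth_rows = [], []
    subtype_cycle = list(tssb_subtypes) if tssb_subtypes is not None else None
    cluster_counter = 0
    for gi in range(n_genomes):
        genome_id = f"G{gi + 1:04d}"
        genes: list[Gene] = []
        n_clusters = int(per_genome(clusters_per_genome, gi))
        for ci in range(n_clusters):
            completeness = per_genome(cog_completeness, gi)
            size = int(per_genome(completeness, ci)) if not np.isscalar(completeness) \
                else int(completeness)
            if size > 10:
                raise ValueError("cog_completeness must be <= 10")
            # TssB (COG3516) kept whenever possible so subtyping has a target
            chosen = list(rng.choice(core, size=size, replace=False))
            if "COG3516" not in chosen and size >= 1:
                chosen[int(rng.integers(size))] = "COG3516"
            rng.shuffle(chosen)
            contig = f"{genome_id}_ctg{ci + 1}"
            pos = int(rng.integers(1, 5000))
            slots: list[str | None] = []
            for j, cog in enumerate(chosen):
                if j > 0:
                    for _ in range(int(rng.integers(0, 3))):  # <= 2 interleaved decoys
                        slots.append(None)
                slots.append(cog)
            subtype = None
            if subtype_cycle:
                subtype = subtype_cycle[cluster_counter % len(subtype_cycle)]
            tssb_ids = []
            for slot in slots:
                length = int(rng.integers(300, 3000))
                cog = slot if slot is not None else str(rng.choice(_DECOY_COGS))
                pid = f"{genome_id}_p{len(genes) + 1:04d}"
                genes.append(Gene(contig=contig, start=pos, end=pos + length - 1,
                                  strand="+" if rng.random() < 0.5 else "-",
                                  cog=cog, protein_id=pid))
                if slot == "COG3516":
                    tssb_ids.append(pid)
                pos += length + int(rng.integers(1, 200))
            truth_rows.append({
                "genome_id": genome_id, "contig": contig,
                "n_core_cogs": len(set(chosen)),
                "callable": len(set(chosen)) >= min_core_cogs,
                "subtype": subtype,
                "tssb_protein_ids": ";".join(tssb_ids),
            })
            cluster_counter += 1
        # background contig of decoy genes only
        contig = f"{genome_id}_ctg0"
        pos = 1
        for _ in range(decoy_gene_count):
            length = int(rng.integers(300, 3000))
            pid = f"{genome_id}_p{len(genes) + 1:04d}"
            genes.append(Gene(contig=contig, start=pos, end=pos + length - 1,
                              strand="+" if rng.random() < 0.5 else "-",
                              cog=str(rng.choice(_DECOY_COGS)), protein_id=pid))
            pos += length + int(rng.integers(1, 200))
        order = rng.permutation(len(genes))
        genomes.append(GenomeAnnotation(genome_id, [genes[i] for i in order]))
    truth = pd.DataFrame(
        truth_rows,
        columns=["genome_id", "contig", "n_core_cogs", "callable",
                 "subtype", "tssb_protein_ids"],
    )
    return genomes, truth


def run_confrontation_experiment(cfg: SimulationConfig) -> CountTable:
    """Simulate dynamics and sequence them: the full synthetic assay."""
    traj = simulate_confrontation(cfg)
    return sample_sequencing_counts(traj, cfg.seq_depth, seed=cfg.seed + 1)
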