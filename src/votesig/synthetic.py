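"""Synthetic multi-model expression data with planted ground truth.

The generator emulates the study design the pipeline targets: five
independent treated-vs-sham contrasts measured on one platform, small
replicate groups (n = 3 by default), log2-scale intensities with a
shared per-gene baseline, a planted consensus set dysregulated in at
least ``min_breadth`` contrasts with log2 effects clearly above the
fold-change threshold, per-model specific DE genes, and decoy genes
whose fold change is large but whose expression sits below the
expression floor of 5.  Companion generators produce promoter sequences
with motif occurrences enriched in a chosen gene set and a GMT gene-set
collection with one planted enriched term, so every downstream stage
has recoverable ground truth.

All generators are pure functions of (params, seed): sub-generators
derive child seeds deterministically from the single global seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from votesig.expression import ExpressionMatrix
from votesig.motifs import ALPHABET, PositionWeightMatrix, PromoterSet, PromoterWindow, reverse_complement
from votesig.enrichment import GeneSetCollection
from votesig.signature import Contrast

__all__ = [
    "SyntheticParams",
    "SyntheticTruth",
    "DEFAULT_CONTRAST_NAMES",
    "generate_dataset",
    "generate_promoters",
    "generate_genesets",
    "default_planted_motif",
    "random_decoy_motifs",
]

# the five insult/treatment models of the emulated design
DEFAULT_CONTRAST_NAMES = ("UC", "Stroke", "DOC", "Alb", "TGFb")

BASELINE_TRUNCATION = 3.0  # log2 floor of the realistic array range
PLANTED_BASELINE_MIN = 6.0  # planted DE genes sit safely above the expression floor
SUBFLOOR_TREATED_CEILING = 4.3  # decoy treated means stay ~5 group-mean SEs below the floor


@dataclass
class SyntheticParams:
    """Generator settings; defaults are the emulated study conditions."""

    n_genes: int = 2000
    n_contrasts: int = 5
    replicates_per_group: int = 3
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    noise_sd: float = 0.25
    n_consensus_up: int = 50
    n_consensus_down: int = 10
    n_specific_per_contrast: int = 20
    n_subfloor_decoys: int = 50
    effect_low: float = 1.5
    effect_high: float = 3.0
    consensus_breadth: int | None = None  # None: sample per gene from {min_breadth..n_contrasts}
    min_breadth: int = 4
    motif_rate_target: float = 0.8
    motif_rate_background: float = 0.05
    promoter_length: int = 1001
    gc_fraction: float = 0.45
    seed: int = 0

    def validate(self) -> None:
        def check(cond: bool, fieldname: str, msg: str) -> None:
            if not cond:
                raise ValueError(f"SyntheticParams.{fieldname}: {msg}")

        check(self.n_genes > 0, "n_genes", "must be positive")
        check(self.n_contrasts > 0, "n_contrasts", "must be positive")
        check(self.replicates_per_group >= 2, "replicates_per_group", "must be >= 2")
        check(self.baseline_sd > 0, "baseline_sd", "must be > 0")
        check(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        check(self.effect_low > 1.0, "effect_low", "must exceed 1.0 (the log2 fold-change threshold)")
        check(self.effect_high >= self.effect_low, "effect_high", "must be >= effect_low")
        for name in ("n_consensus_up", "n_consensus_down", "n_specific_per_contrast", "n_subfloor_decoys"):
            check(getattr(self, name) >= 0, name, "must be >= 0")
        planted = (
            self.n_consensus_up
            + self.n_consensus_down
            + self.n_contrasts * self.n_specific_per_contrast
            + self.n_subfloor_decoys
        )
        check(planted <= self.n_genes, "n_genes", f"planted genes ({planted}) exceed n_genes ({self.n_genes})")
        check(1 <= self.min_breadth <= self.n_contrasts, "min_breadth", "must lie in [1, n_contrasts]")
        if self.consensus_breadth is not None:
            check(
                self.min_breadth <= self.consensus_breadth <= self.n_contrasts,
                "consensus_breadth",
                "must lie in [min_breadth, n_contrasts]",
            )
        check(0 <= self.motif_rate_target <= 1, "motif_rate_target", "must be a probability")
        check(0 <= self.motif_rate_background <= 1, "motif_rate_background", "must be a probability")
        check(self.promoter_length > 0, "promoter_length", "must be positive")
        check(0 < self.gc_fraction < 1, "gc_fraction", "must lie in (0, 1)")


@dataclass
class SyntheticTruth:
    """Planted ground truth recorded by the generators."""

    consensus_up: set[str] = field(default_factory=set)
    consensus_down: set[str] = field(default_factory=set)
    specific: dict[str, set[str]] = field(default_factory=dict)
    subfloor: set[str] = field(default_factory=set)
    motif_genes: set[str] = field(default_factory=set)
    enriched_term: str | None = None
    per_gene_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    universe: list[str] = field(default_factory=list)
    seed: int = 0

    def to_txt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"seed\t{self.seed}\n")
            fh.write("consensus_up\t" + ",".join(sorted(self.consensus_up)) + "\n")
            fh.write("consensus_down\t" + ",".join(sorted(self.consensus_down)) + "\n")
            for contrast in sorted(self.specific):
                fh.write(f"specific:{contrast}\t" + ",".join(sorted(self.specific[contrast])) + "\n")
            fh.write("subfloor\t" + ",".join(sorted(self.subfloor)) + "\n")
            fh.write("motif_genes\t" + ",".join(sorted(self.motif_genes)) + "\n")
            fh.write(f"enriched_term\t{self.enriched_term or ''}\n")


def _child_rng(seed: int, stream: int) -> np.random.Generator:
    """Deterministic child generator: stream index spawned off the
    global seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def generate_dataset(
    params: SyntheticParams,
) -> tuple[list[ExpressionMatrix], list[Contrast], SyntheticTruth]:
    """Generate one expression matrix per contrast plus planted truth.

    Gene baselines are drawn once and shared across contrasts (one
    platform, several experiments); per-contrast replicate noise is
    independent N(0, noise_sd).  Treated group means equal baseline plus
    the planted log2 effect where one is planted.
    """
    params.validate()
    genes = [f"g{i:05d}" for i in range(params.n_genes)]
    contrast_names = (
        list(DEFAULT_CONTRAST_NAMES[: params.n_contrasts])
        if params.n_contrasts <= len(DEFAULT_CONTRAST_NAMES)
        else [f"M{i:02d}" for i in range(params.n_contrasts)]
    )

    rng_roles = _child_rng(params.seed, 0)
    rng_baseline = _child_rng(params.seed, 1)
    rng_effects = _child_rng(params.seed, 2)
    rng_noise = _child_rng(params.seed, 3)

    order = rng_roles.permutation(params.n_genes)
    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        picked = [genes[i] for i in order[cursor : cursor + n]]
        cursor += n
        return picked

    up_genes = take(params.n_consensus_up)
    down_genes = take(params.n_consensus_down)
    specific = {name: set(take(params.n_specific_per_contrast)) for name in contrast_names}
    subfloor_genes = take(params.n_subfloor_decoys)

    baselines = pd.Series(
        rng_baseline.normal(params.baseline_mean, params.baseline_sd, size=params.n_genes),
        index=genes,
    ).clip(lower=BASELINE_TRUNCATION)
    planted_expressed = set(up_genes) | set(down_genes) | set().union(*specific.values())
    for g in planted_expressed:
        baselines[g] = max(baselines[g], PLANTED_BASELINE_MIN)
    for g in subfloor_genes:
        baselines[g] = rng_baseline.uniform(BASELINE_TRUNCATION, BASELINE_TRUNCATION + 0.2)

    truth = SyntheticTruth(
        consensus_up=set(up_genes),
        consensus_down=set(down_genes),
        specific=specific,
        subfloor=set(subfloor_genes),
        universe=list(genes),
        seed=params.seed,
    )

    def draw_effect() -> float:
        return float(rng_effects.uniform(params.effect_low, params.effect_high))

    def carrying_contrasts() -> list[str]:
        breadth = (
            params.consensus_breadth
            if params.consensus_breadth is not None
            else int(rng_effects.integers(params.min_breadth, params.n_contrasts + 1))
        )
        idx = rng_effects.choice(params.n_contrasts, size=breadth, replace=False)
        return [contrast_names[i] for i in sorted(idx)]

    for g in up_genes:
        for c in carrying_contrasts():
            truth.per_gene_effects[(g, c)] = draw_effect()
    for g in down_genes:
        for c in carrying_contrasts():
            truth.per_gene_effects[(g, c)] = -draw_effect()
    for c, gset in specific.items():
        for g in sorted(gset):
            sign = 1.0 if rng_effects.random() < 0.5 else -1.0
            truth.per_gene_effects[(g, c)] = sign * draw_effect()
    # decoys: |log2FC| > 1 in every contrast, but treated mean pinned below the floor
    for g in subfloor_genes:
        cap = SUBFLOOR_TREATED_CEILING - baselines[g]
        for c in contrast_names:
            truth.per_gene_effects[(g, c)] = float(rng_effects.uniform(1.05, cap))

    matrices: list[ExpressionMatrix] = []
    contrasts: list[Contrast] = []
    reps = params.replicates_per_group
    for c in contrast_names:
        effect = pd.Series(0.0, index=genes)
        for g in genes:
            e = truth.per_gene_effects.get((g, c))
            if e is not None:
                effect[g] = e
        sham_cols = [f"{c}_sham_{r+1}" for r in range(reps)]
        trt_cols = [f"{c}_treated_{r+1}" for r in range(reps)]
        noise = rng_noise.normal(0.0, params.noise_sd, size=(params.n_genes, 2 * reps))
        sham_vals = baselines.to_numpy()[:, None] + noise[:, :reps]
        trt_vals = (baselines + effect).to_numpy()[:, None] + noise[:, reps:]
        values = pd.DataFrame(
            np.hstack([sham_vals, trt_vals]), index=genes, columns=sham_cols + trt_cols
        )
        group_of = {s: "sham" for s in sham_cols} | {s: "treated" for s in trt_cols}
        matrices.append(ExpressionMatrix(values=values, group_of=group_of))
        contrasts.append(Contrast(name=c, treated_group="treated", control_group="sham"))
    return matrices, contrasts, truth


def default_planted_motif() -> PositionWeightMatrix:
    """A sharply-peaked 10-bp synthetic motif (NFkB-like consensus
    GGGACTTTCC) used as the default planted promoter signal."""
    consensus = "GGGACTTTCC"
    counts = np.full((4, len(consensus)), 5.0)
    for j, base in enumerate(consensus):
        counts[ALPHABET.index(base), j] = 85.0
    return PositionWeightMatrix(motif_id="SYN_NFKB_LIKE", counts=counts)


def random_decoy_motifs(n: int, length: int, seed: int) -> list[PositionWeightMatrix]:
    """Random sharply-peaked decoy motifs for enrichment ranking tests."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        counts = np.full((4, length), 5.0)
        for j in range(length):
            counts[rng.integers(0, 4), j] = 85.0
        out.append(PositionWeightMatrix(motif_id=f"DECOY_{i:02d}", counts=counts))
    return out


def generate_promoters(
    truth: SyntheticTruth,
    params: SyntheticParams,
    motif: PositionWeightMatrix | None = None,
) -> PromoterSet:
    """One promoter per universe gene: i.i.d. background at the
    configured GC fraction, with an exact motif-consensus occurrence
    planted at a random position/strand with probability
    ``motif_rate_target`` for ``truth.motif_genes`` (defaulting to the
    up-consensus set) and ``motif_rate_background`` otherwise.

    Plant positions are recorded in the returned set's ``plants`` map.
    """
    params.validate()
    motif = motif or default_planted_motif()
    if params.promoter_length < motif.length:
        raise ValueError(
            f"promoter_length {params.promoter_length} shorter than motif length {motif.length}"
        )
    if not truth.motif_genes:
        truth.motif_genes = set(truth.consensus_up)
    rates_active = params.motif_rate_target > 0 or params.motif_rate_background > 0
    if truth.motif_genes and rates_active and params.motif_rate_target <= params.motif_rate_background:
        raise ValueError(
            "motif_rate_target must exceed motif_rate_background for recoverable enrichment"
        )
    rng = _child_rng(truth.seed, 10)
    gc = params.gc_fraction
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    consensus = motif.consensus()
    L = params.promoter_length
    windows: dict[str, PromoterWindow] = {}
    plants: dict[str, tuple[int, str]] = {}
    bases = np.array(list(ALPHABET))
    for g in truth.universe:
        seq_arr = rng.choice(bases, size=L, p=probs)
        rate = params.motif_rate_target if g in truth.motif_genes else params.motif_rate_background
        if rng.random() < rate:
            pos = int(rng.integers(0, L - motif.length + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            site = consensus if strand == "+" else reverse_complement(consensus)
            seq_arr[pos : pos + motif.length] = list(site)
            plants[g] = (pos, strand)
        half = (L - 1) // 2
        windows[g] = PromoterWindow(
            gene_id=g,
            sequence="".join(seq_arr),
            rel_start=-half,
            rel_end=L - 1 - half,
        )
    return PromoterSet(windows=windows, plants=plants)


def generate_genesets(
    truth: SyntheticTruth,
    n_terms: int = 20,
    term_size_range: tuple[int, int] = (15, 40),
    seed: int | None = None,
    consensus_fraction: float = 0.5,
) -> GeneSetCollection:
    """GMT-serializable collection with one planted enriched term.

    The designated term draws ``consensus_fraction`` of its members from
    the up-consensus set (capped at its size) and fills the rest at
    random; the remaining terms are uniform draws from the universe.
    Records the designated term id in ``truth.enriched_term``.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    lo, hi = term_size_range
    if not 1 <= lo <= hi <= len(truth.universe):
        raise ValueError(f"term_size_range {term_size_range} exceeds the universe of {len(truth.universe)}")
    rng = _child_rng(truth.seed if seed is None else seed, 20)
    universe = np.array(truth.universe)
    consensus_pool = sorted(truth.consensus_up)
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for i in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        term_id = f"T{i:04d}"
        if i == 0:
            n_cons = min(int(round(consensus_fraction * size)), len(consensus_pool))
            members = set(
                rng.choice(consensus_pool, size=n_cons, replace=False)
            ) if n_cons else set()
            fillers = [g for g in universe if g not in members]
            members |= set(rng.choice(fillers, size=size - len(members), replace=False))
            terms[term_id] = ("planted enriched term", frozenset(members))
            truth.enriched_term = term_id
        else:
            members = rng.choice(universe, size=size, replace=False)
            terms[term_id] = (f"random term {i}", frozenset(members))
    return GeneSetCollection(terms=terms)
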