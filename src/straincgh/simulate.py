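"""Synthetic strain panels with known ground truth.

Emulates a two-channel CGH experiment against a reference genome laid out
like *Cupriavidus metallidurans* CH34: ~6205 probed CDS over four replicons
(two chromosomes and two megaplasmids), a panel of strains split into two
gene-content groups that carry the planted genomic islands with different
probabilities, plasmid-cured derivative strains of exactly known content for
cutoff calibration, and noisy spot intensities with per-print-tip and
intensity-dependent dye bias.

Every stochastic operation takes an explicit integer seed; identical
(config, seed) pairs give identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._utils import ConfigError, child_rng
from .io import ArrayScan, GeneTable

BACKBONE = "backbone"
ISLAND = "island"
PLASMID_BACKBONE = "plasmid-backbone"


@dataclass(frozen=True)
class RegionSpec:
    """A planted contiguous region of the reference genome (truth record)."""

    name: str
    replicon: str
    cls: str  # BACKBONE | ISLAND | PLASMID_BACKBONE
    first_index: int  # global locus index, inclusive
    last_index: int
    locus_tags: tuple[str, ...]

    @property
    def n_genes(self) -> int:
        return len(self.locus_tags)


@dataclass
class GenomeModel:
    """Reference genome layout: replicons, ordered loci, planted regions."""

    replicons: list[tuple[str, int]]
    loci: pd.DataFrame  # locus_tag, replicon, start, end, strand, probe_id
    regions: dict[str, RegionSpec]

    @property
    def locus_tags(self) -> list[str]:
        return list(self.loci["locus_tag"])

    def islands(self) -> list[RegionSpec]:
        return [r for r in self.regions.values() if r.cls == ISLAND]

    def gene_table(self) -> GeneTable:
        sets = {name: list(r.locus_tags) for name, r in self.regions.items()
                if r.cls != BACKBONE}
        return GeneTable(records=self.loci.copy(), gene_sets=sets)


@dataclass(frozen=True)
class StrainContent:
    """One strain's true gene content (a subset of the reference loci)."""

    strain_id: str
    present: frozenset
    group: str  # "I" | "II" | "derivative" | "reference"


@dataclass(frozen=True)
class NoiseModel:
    """Intensity model for simulated scans.

    Background is Normal(background_mean, background_sd); a present locus
    adds a bright signal, lognormal with mean ``signal_mean`` and log-sd
    ``signal_log_sd`` (spot intensities of hybridizing probes are tightly
    log-normal; a 20-fold cutoff only makes sense when present spots sit
    far above background). Per-print-tip offsets and an A-dependent dye
    trend multiply the test channel on the log2 scale; a small fraction of
    spots is flagged bad.
    """

    background_mean: float = 100.0
    background_sd: float = 10.0
    signal_mean: float = 20000.0
    signal_log_sd: float = 0.25
    tip_bias_amplitude: float = 0.1
    dye_intercept: float = 0.1
    dye_slope: float = 0.05
    flag_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.background_mean <= 0 or self.background_sd < 0 or self.signal_mean <= 0:
            raise ConfigError("background_mean, signal_mean must be > 0; background_sd >= 0")
        if not 0 <= self.flag_rate < 1:
            raise ConfigError("flag_rate must be in [0, 1)")


@dataclass(frozen=True)
class IslandPlan:
    replicon: str
    count: int
    size_range: tuple[int, int] = (5, 150)  # genes per island


@dataclass(frozen=True)
class GeneratorConfig:
    """Genome/panel layout. Defaults mirror the CH34-like study design:
    6205 loci on CHR1/CHR2/pMOL28/pMOL30, 13 + 5 planted chromosomal
    islands of 5-150 genes, and 7 + 9 strains in the two content groups."""

    replicons: tuple[tuple[str, int], ...] = (
        ("CHR1", 3_928_089),
        ("CHR2", 2_580_084),
        ("pMOL28", 171_459),
        ("pMOL30", 233_720),
    )
    loci_per_replicon: tuple[tuple[str, int], ...] = (
        ("CHR1", 3553),
        ("CHR2", 2270),
        ("pMOL28", 166),
        ("pMOL30", 216),
    )
    island_plans: tuple[IslandPlan, ...] = (
        IslandPlan("CHR1", 13),
        IslandPlan("CHR2", 5),
    )
    plasmid_replicons: tuple[str, ...] = ("pMOL28", "pMOL30")
    min_island_separation: int = 6  # backbone loci between/around islands
    n_group_i: int = 7
    n_group_ii: int = 9
    island_presence: tuple[tuple[str, float], ...] = (("I", 0.9), ("II", 0.2))
    plasmid_presence: tuple[tuple[str, float], ...] = (("I", 1.0), ("II", 1.0))
    island_flip_rate: float = 0.05  # per-strain deviation from the group template
    dropout: float = 0.02  # per-locus loss inside a carried region
    grid: tuple[int, int] = (4, 4)  # print-tip blocks

    @property
    def n_loci(self) -> int:
        return sum(n for _, n in self.loci_per_replicon)


def default_config() -> GeneratorConfig:
    return GeneratorConfig()


# ---------------------------------------------------------------------------
# genome model
# ---------------------------------------------------------------------------


def build_genome_model(config: GeneratorConfig, seed: int) -> GenomeModel:
    """Lay out loci on each replicon and plant the configured regions.

    Island sizes are drawn from the plan's range; islands are separated by
    at least ``min_island_separation`` backbone loci (so neighbouring
    planted islands can never fuse under the default scanner gap). Each
    plasmid replicon becomes a single plasmid-backbone region.
    """
    rng = child_rng(seed, 0)
    rep_len = dict(config.replicons)
    plans: dict[str, IslandPlan] = {}
    for plan in config.island_plans:
        if plan.replicon not in rep_len:
            raise ConfigError(f"island plan names unknown replicon {plan.replicon!r}")
        plans[plan.replicon] = plan

    rows = []
    regions: dict[str, RegionSpec] = {}
    offset = 0
    for rep, n in config.loci_per_replicon:
        if rep not in rep_len:
            raise ConfigError(f"loci_per_replicon names unknown replicon {rep!r}")
        slot = rep_len[rep] // n
        if slot < 2:
            raise ConfigError(f"replicon {rep} too short for {n} loci")
        gene_len = max(1, int(slot * 0.85))
        strands = rng.choice(["+", "-"], size=n)
        for i in range(n):
            start = i * slot + 1
            rows.append(
                {
                    "locus_tag": f"{rep}_{i + 1:04d}",
                    "replicon": rep,
                    "start": start,
                    "end": start + gene_len - 1,
                    "strand": strands[i],
                    "probe_id": f"P{offset + i + 1:06d}",
                }
            )
        # plant islands on this replicon
        plan = plans.get(rep)
        if plan is not None and plan.count > 0:
            lo, hi = plan.size_range
            if lo < 1 or hi < lo:
                raise ConfigError(f"bad island size range {plan.size_range}")
            sizes = rng.integers(lo, hi + 1, size=plan.count)
            sep = config.min_island_separation
            need = int(sizes.sum()) + sep * (plan.count + 1)
            if need > n:
                raise ConfigError(
                    f"{plan.count} islands of up to {hi} genes do not fit on {rep} ({n} loci)"
                )
            slack = n - need
            extra = rng.multinomial(slack, [1.0 / (plan.count + 1)] * (plan.count + 1))
            cursor = sep + int(extra[0])
            for k, size in enumerate(sizes):
                name = f"{rep}-GI{k + 1:02d}"
                first = offset + cursor
                last = first + int(size) - 1
                tags = tuple(rows[j]["locus_tag"] for j in range(first, last + 1))
                regions[name] = RegionSpec(name, rep, ISLAND, first, last, tags)
                cursor += int(size) + sep + int(extra[k + 1])
        if rep in config.plasmid_replicons:
            tags = tuple(rows[j]["locus_tag"] for j in range(offset, offset + n))
            regions[rep] = RegionSpec(rep, rep, PLASMID_BACKBONE, offset, offset + n - 1, tags)
        offset += n

    loci = pd.DataFrame(rows)
    return GenomeModel(replicons=list(config.replicons), loci=loci, regions=regions)


# ---------------------------------------------------------------------------
# strain contents
# ---------------------------------------------------------------------------


def assign_strain_content(
    model: GenomeModel,
    n_group_i: int,
    n_group_ii: int,
    island_presence: Mapping[str, float],
    seed: int,
    dropout: float = 0.02,
    plasmid_presence: Mapping[str, float] | None = None,
    island_flip_rate: float = 0.05,
) -> list[StrainContent]:
    """Draw per-strain gene contents under a lineage-style inheritance model.

    Backbone loci are present in every strain. Islands are inherited as
    blocks: each group first draws an ancestral *template* (island included
    with probability (p - eps)/(1 - 2 eps), where p is the group's carriage
    probability and eps = ``island_flip_rate``); each strain then copies
    the template, flipping every island's state independently with
    probability eps, so group members share most of their island
    complement while the marginal per-strain carriage stays exactly p.
    A carried region is subject to independent per-locus ``dropout``.
    Plasmid-backbone regions behave the same way under
    ``plasmid_presence`` (default: carried by all strains).
    """
    if n_group_i + n_group_ii == 0:
        raise ConfigError("need at least one strain")
    for p in island_presence.values():
        if not 0.0 <= p <= 1.0:
            raise ConfigError("island presence probabilities must lie in [0, 1]")
    if not 0.0 <= island_flip_rate < 0.5:
        raise ConfigError("island_flip_rate must lie in [0, 0.5)")
    if plasmid_presence is None:
        plasmid_presence = {g: 1.0 for g in island_presence}
    rng = child_rng(seed, 1)

    all_tags = model.locus_tags
    region_tags: set[str] = set()
    for r in model.regions.values():
        if r.cls in (ISLAND, PLASMID_BACKBONE):
            region_tags.update(r.locus_tags)
    backbone = [t for t in all_tags if t not in region_tags]

    def template_prob(p: float) -> float:
        if p <= 0.0 or p >= 1.0 or island_flip_rate == 0.0:
            return float(p)
        return min(max((p - island_flip_rate) / (1.0 - 2.0 * island_flip_rate), 0.0), 1.0)

    regions = list(model.regions.values())
    templates: dict[tuple[str, str], bool] = {}
    for group in ("I", "II"):
        for region in regions:
            if region.cls == ISLAND:
                p = island_presence.get(group, 0.0)
            elif region.cls == PLASMID_BACKBONE:
                p = plasmid_presence.get(group, 1.0)
            else:
                continue
            templates[(group, region.name)] = bool(rng.random() < template_prob(p))

    def flip(p: float) -> float:
        # degenerate probabilities stay deterministic: {I:1.0, II:0.0} must be exact
        return island_flip_rate if 0.0 < p < 1.0 else 0.0

    contents: list[StrainContent] = []
    labels = [("I", k + 1) for k in range(n_group_i)] + [
        ("II", k + 1) for k in range(n_group_ii)
    ]
    for group, k in labels:
        present = set(backbone)
        for region in regions:
            if region.cls == ISLAND:
                p = island_presence.get(group, 0.0)
            elif region.cls == PLASMID_BACKBONE:
                p = plasmid_presence.get(group, 1.0)
            else:
                present.update(region.locus_tags)
                continue
            carried = templates[(group, region.name)]
            if rng.random() < flip(p):
                carried = not carried
            if carried:
                keep = rng.random(region.n_genes) >= dropout
                present.update(t for t, k_ in zip(region.locus_tags, keep) if k_)
        contents.append(
            StrainContent(strain_id=f"{group}{k:02d}", present=frozenset(present), group=group)
        )
    return contents


def reference_content(model: GenomeModel, strain_id: str = "REF") -> StrainContent:
    """The reference strain carries every probed locus."""
    return StrainContent(strain_id=strain_id, present=frozenset(model.locus_tags),
                         group="reference")


def make_validation_derivative(
    reference: StrainContent, region_name: str, model: GenomeModel
) -> StrainContent:
    """A copy of ``reference`` cured of one named region (e.g. a megaplasmid).

    These derivatives have exactly known content and anchor the
    false-positive / false-negative trade-off when calibrating the
    fold-change cutoff. Idempotent: re-deleting the same region is a no-op.
    """
    if region_name not in model.regions:
        raise ConfigError(f"unknown region {region_name!r}")
    region = model.regions[region_name]
    suffix = f"-d{region_name}"
    strain_id = (
        reference.strain_id
        if reference.strain_id.endswith(suffix)
        else reference.strain_id + suffix
    )
    return StrainContent(
        strain_id=strain_id,
        present=reference.present - set(region.locus_tags),
        group="derivative",
    )


def truth_frame(contents: Sequence[StrainContent], model: GenomeModel) -> pd.DataFrame:
    """Long-form truth table (strain, locus_tag, present)."""
    rows = []
    for c in contents:
        for tag in model.locus_tags:
            rows.append((c.strain_id, tag, tag in c.present))
    return pd.DataFrame(rows, columns=["strain", "locus_tag", "present"])


def truth_presence_matrix(model: GenomeModel, contents: Sequence[StrainContent]):
    """Noise-free presence matrix straight from the generated truth."""
    from .io import PresenceMatrix

    calls = pd.DataFrame(
        {c.strain_id: [t in c.present for t in model.locus_tags] for c in contents},
        index=model.locus_tags,
        dtype="boolean",
    )
    return PresenceMatrix(calls=calls)


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------


def _signal(rng: np.random.Generator, n: int, noise: NoiseModel) -> np.ndarray:
    if noise.signal_log_sd == 0:
        return np.full(n, noise.signal_mean)
    mu_log = math.log(noise.signal_mean) - noise.signal_log_sd**2 / 2
    return rng.lognormal(mean=mu_log, sigma=noise.signal_log_sd, size=n)


def simulate_scan(
    model: GenomeModel,
    content: StrainContent,
    noise: NoiseModel,
    seed: int,
    grid: tuple[int, int] = (4, 4),
) -> ArrayScan:
    """Simulate one two-channel hybridization against the reference array.

    Test-channel foreground = background draw + signal (present loci only),
    multiplied on the log2 scale by the spot's print-tip offset and an
    A-dependent dye trend; the reference channel always carries signal
    (the reference strain has every probe). Background columns are
    independent background draws; ``flag_rate`` of spots get flag -100.
    """
    tags = model.locus_tags
    unknown = content.present - set(tags)
    if unknown:
        raise ConfigError(f"content names loci outside the model, e.g. {sorted(unknown)[0]!r}")
    rng = child_rng(seed, 2)
    n = len(tags)
    n_blocks = grid[0] * grid[1]
    per_block = -(-n // n_blocks)
    ncols = max(1, math.isqrt(per_block - 1) + 1) if per_block > 1 else 1
    idx = np.arange(n)
    block = idx // per_block + 1
    within = idx % per_block
    row = within // ncols + 1
    col = within % ncols + 1

    present = np.array([t in content.present for t in tags])
    draw = lambda: np.clip(rng.normal(noise.background_mean, noise.background_sd, n), 1.0, None)
    fg_test0 = draw() + np.where(present, _signal(rng, n, noise), 0.0)
    bg_test = draw()
    fg_ref = draw() + _signal(rng, n, noise)
    bg_ref = draw()

    a0 = 0.5 * (np.log2(fg_test0) + np.log2(fg_ref))
    tip = rng.uniform(-noise.tip_bias_amplitude, noise.tip_bias_amplitude, n_blocks)
    m_bias = tip[block - 1] + noise.dye_intercept + noise.dye_slope * (a0 - a0.mean())
    fg_test = fg_test0 * np.exp2(m_bias)

    flag = np.where(rng.random(n) < noise.flag_rate, -100, 0)
    spots = pd.DataFrame(
        {
            "probe_id": model.loci["probe_id"].to_numpy(),
            "block": block,
            "row": row,
            "column": col,
            "fg_test": fg_test,
            "bg_test": bg_test,
            "fg_ref": fg_ref,
            "bg_ref": bg_ref,
            "flag": flag,
        }
    )
    return ArrayScan(strain_id=content.strain_id, spots=spots)


def simulate_panel(
    config: GeneratorConfig, noise: NoiseModel, seed: int, derivatives: Sequence[str] = (),
) -> tuple[GenomeModel, list[StrainContent], list[ArrayScan]]:
    """Full study design: genome, strain panel (plus reference and any cured
    derivatives), and one scan per non-reference strain."""
    model = build_genome_model(config, seed)
    contents = assign_strain_content(
        model,
        config.n_group_i,
        config.n_group_ii,
        dict(config.island_presence),
        seed,
        dropout=config.dropout,
        plasmid_presence=dict(config.plasmid_presence),
        island_flip_rate=config.island_flip_rate,
    )
    ref = reference_content(model)
    for region_name in derivatives:
        contents.append(make_validation_derivative(ref, region_name, model))
    scans = [
        simulate_scan(model, c, noise, seed + 10_000 + i, grid=config.grid)
        for i, c in enumerate(contents)
    ]
    return model, contents, scans
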