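"""Synthetic genomes, annotation tracks, gene tables and labelled CNV sets.

The generator emulates the class-conditional structure that separates
pathogenic from benign CNVs in real cohorts: pathogenic (``mr``) CNVs
are roughly an order of magnitude larger (log-normal lengths, mean ~7 Mb
versus ~0.5 Mb), mostly losses, gene- and SINE-enriched, and ~80% of
them contain at least one gene whose mouse knockout shows a nervous-
system phenotype; benign CNVs are enriched in LINE elements and
segmental duplications and only rarely (~5%) contain such a gene.

Elements are placed by a homogeneous Poisson process with density-
hotspot patches per track; CNV placement is biased toward or away from
those patches by per-class multipliers via rejection sampling.  Genes
with the nervous-system (MGI) and neurodegeneration-pathway (KEGG)
flags are confined to "neuro region" patches so that both flag-positive
and flag-negative placements exist for CNVs of every size.

Everything is driven by a single integer seed and fully reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import (
    AnnotationTrack,
    CnvRecord,
    GeneIndex,
    GeneRecord,
    build_feature_matrix,
    write_cnv_table,
    write_gene_table,
)

Patches = dict[str, list[tuple[int, int]]]  # chrom -> [(start, end)]


@dataclass(frozen=True)
class SynthTrackSpec:
    """One element class: mean genome-wide density (elements per bp),
    element length distribution (log-normal), and hotspot patches where
    the density is multiplied."""

    density: float
    mean_length: float
    length_sigma: float = 0.5
    hotspot_fraction: float = 0.2
    hotspot_multiplier: float = 3.0
    patch_block: int = 2_000_000

    def __post_init__(self) -> None:
        if self.density < 0:
            raise ValueError("density must be >= 0")
        if not 0 <= self.hotspot_fraction <= 1:
            raise ValueError("hotspot_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SynthGenomeSpec:
    """Layout of the synthetic genome.

    Densities are calibrated to the human genome (one LINE per ~4 kb,
    one SINE per ~2.5 kb, ~6.5 genes per Mb, sparse segmental
    duplications); chromosome lengths are scaled down so that multi-Mb
    pathogenic CNVs still fit many times over.
    """

    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 50_000_000, "chr2": 40_000_000, "chr3": 30_000_000}
    )
    tracks: Mapping[str, SynthTrackSpec] = field(
        default_factory=lambda: {
            "LINE": SynthTrackSpec(density=2.4e-4, mean_length=3_000),
            "SINE": SynthTrackSpec(density=4.0e-4, mean_length=300),
            "segdup": SynthTrackSpec(
                density=8.0e-6, mean_length=20_000,
                hotspot_fraction=0.1, hotspot_multiplier=6.0,
            ),
        }
    )
    gene_track: SynthTrackSpec = field(
        default_factory=lambda: SynthTrackSpec(
            density=6.5e-6, mean_length=30_000,
            hotspot_fraction=0.25, hotspot_multiplier=3.0,
        )
    )
    neuro_region_fraction: float = 0.25
    neuro_block: int = 5_000_000
    mgi_within_neuro: float = 0.35   # P(mgi_nervous) for genes inside neuro regions
    kegg_within_neuro: float = 0.12  # P(kegg_neuro) for genes inside neuro regions
    rate_missing: float = 0.2        # genes lacking dN/dS annotation
    expr_missing: float = 0.15       # genes lacking an expression profile
    seed: int = 0

    def __post_init__(self) -> None:
        for name, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")


@dataclass(frozen=True)
class SynthClassSpec:
    """Class-conditional CNV generation parameters.

    ``length_median_bp``/``length_sigma`` parameterise the log-normal
    length distribution (strictly positive and heavy-tailed, matching
    the 10 kb to multi-Mb range seen on arrays).  ``multipliers`` bias
    placement toward (>1) or away from (<1) each track's hotspot
    patches; ``gene_multiplier`` does the same for gene-dense patches.
    ``mgi_target`` is the fraction of CNVs required to contain at least
    one nervous-system-phenotype gene.
    """

    length_median_bp: float
    length_sigma: float
    multipliers: Mapping[str, float]
    gene_multiplier: float
    mgi_target: float
    loss_fraction: float = 0.5
    min_length_bp: int = 10_000

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.multipliers.values()) or self.gene_multiplier <= 0:
            raise ValueError("placement multipliers must be > 0")
        if not 0 <= self.mgi_target <= 1:
            raise ValueError("mgi_target must be in [0, 1]")


#: Pathogenic CNVs: log-normal median 3.5 Mb (mean ~6.8 Mb), mostly losses,
#: SINE/gene-seeking, segdup/LINE-avoiding, 80% MGI-positive.
MR_CLASS_SPEC = SynthClassSpec(
    length_median_bp=3_500_000,
    length_sigma=1.15,
    multipliers={"LINE": 0.7, "SINE": 2.5, "segdup": 0.4},
    gene_multiplier=2.0,
    mgi_target=0.80,
    loss_fraction=0.7,
)

#: Benign CNVs: log-normal median ~0.2 Mb (mean ~0.47 Mb), LINE/segdup-
#: seeking, gene-poor, rarely (5%) MGI-positive.
BENIGN_CLASS_SPEC = SynthClassSpec(
    length_median_bp=205_000,
    length_sigma=1.3,
    multipliers={"LINE": 2.5, "SINE": 0.8, "segdup": 4.0},
    gene_multiplier=0.6,
    mgi_target=0.05,
    loss_fraction=0.5,
)

DEFAULT_CLASS_SPECS: dict[str, SynthClassSpec] = {
    "mr": MR_CLASS_SPEC,
    "benign": BENIGN_CLASS_SPEC,
}


@dataclass
class SynthGenome:
    """A generated genome: chromosome map, element tracks, genes, and the
    hotspot patch layout used to bias CNV placement."""

    spec: SynthGenomeSpec
    chrom_lengths: dict[str, int]
    tracks: dict[str, AnnotationTrack]
    genes: GeneIndex
    patches: dict[str, Patches]   # track name (incl. "gene") -> patches
    neuro_regions: Patches

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())


# ---------------------------------------------------------------------------
# Patch layout and weighted placement
# ---------------------------------------------------------------------------

def _make_patches(
    chrom_lengths: Mapping[str, int], fraction: float, block: int, rng: np.random.Generator
) -> Patches:
    """Mark a random subset of fixed-size blocks as hotspot patches,
    covering ~``fraction`` of each chromosome."""
    patches: Patches = {}
    for chrom, length in chrom_lengths.items():
        n_blocks = max(length // block, 1)
        n_pick = int(round(fraction * n_blocks))
        picked = rng.choice(n_blocks, size=n_pick, replace=False) if n_pick else []
        ivs = sorted((int(b) * block, min(int(b + 1) * block, length)) for b in picked)
        patches[chrom] = ivs
    return patches


def _coverage(patches: Patches, chrom: str, start: int, end: int) -> float:
    """Fraction of [start, end) covered by the patch set."""
    cov = 0
    for s, e in patches.get(chrom, []):
        cov += max(0, min(e, end) - max(s, start))
    return cov / (end - start)


def _sample_positions(
    length: int, patches: Sequence[tuple[int, int]], multiplier: float,
    n: int, rng: np.random.Generator,
) -> np.ndarray:
    """Sample ``n`` positions on [0, length) with density ``multiplier``
    inside the patches relative to outside."""
    bounds = [0]
    weights = []
    pos = 0
    for s, e in patches:
        if s > pos:
            bounds.append(s)
            weights.append(1.0)
        bounds.append(e)
        weights.append(multiplier)
        pos = e
    if pos < length:
        bounds.append(length)
        weights.append(1.0)
    starts = np.array(bounds[:-1], dtype=float)
    lens = np.diff(np.array(bounds, dtype=float))
    w = np.array(weights) * lens
    cum = np.concatenate([[0.0], np.cumsum(w)])
    u = rng.random(n) * cum[-1]
    seg = np.searchsorted(cum, u, side="right") - 1
    seg = np.clip(seg, 0, len(lens) - 1)
    frac = (u - cum[seg]) / np.maximum(w[seg], 1e-300)
    return (starts[seg] + frac * lens[seg]).astype(np.int64)


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------

def generate_genome(spec: SynthGenomeSpec | None = None, seed: int | None = None) -> SynthGenome:
    """Generate the chromosome map, element tracks and gene table.

    Per track and chromosome the element count is Poisson with mean
    ``density x effective length`` (hotspot patches weigh in with their
    multiplier), and element positions fall uniformly within the
    weighted mixture of patch and background sequence.
    """
    spec = spec or SynthGenomeSpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    chrom_lengths = dict(spec.chrom_lengths)
    patches: dict[str, Patches] = {}
    tracks: dict[str, AnnotationTrack] = {}
    for name, tspec in spec.tracks.items():
        patches[name] = _make_patches(chrom_lengths, tspec.hotspot_fraction, tspec.patch_block, rng)
        intervals: list[tuple[str, int, int]] = []
        for chrom, length in chrom_lengths.items():
            cov = _coverage(patches[name], chrom, 0, length)
            eff = length * (1 - cov) + length * cov * tspec.hotspot_multiplier
            n = rng.poisson(tspec.density * eff)
            if n == 0:
                continue
            pos = _sample_positions(length, patches[name][chrom], tspec.hotspot_multiplier, n, rng)
            elen = np.maximum(
                rng.lognormal(np.log(tspec.mean_length), tspec.length_sigma, n), 10
            ).astype(np.int64)
            ends = np.minimum(pos + elen, length)
            keep = ends > pos
            intervals.extend(
                (chrom, int(s), int(e)) for s, e in zip(pos[keep], ends[keep])
            )
        tracks[name] = AnnotationTrack(name, intervals)

    gspec = spec.gene_track
    patches["gene"] = _make_patches(chrom_lengths, gspec.hotspot_fraction, gspec.patch_block, rng)
    neuro = _make_patches(chrom_lengths, spec.neuro_region_fraction, spec.neuro_block, rng)
    genes: list[GeneRecord] = []
    gi = 0
    for chrom, length in chrom_lengths.items():
        cov = _coverage(patches["gene"], chrom, 0, length)
        eff = length * (1 - cov) + length * cov * gspec.hotspot_multiplier
        n = rng.poisson(gspec.density * eff)
        if n == 0:
            continue
        pos = _sample_positions(length, patches["gene"][chrom], gspec.hotspot_multiplier, n, rng)
        glen = np.maximum(
            rng.lognormal(np.log(gspec.mean_length), gspec.length_sigma, n), 200
        ).astype(np.int64)
        for s, l in zip(np.sort(pos), glen):
            e = min(int(s + l), length)
            if e <= s:
                continue
            in_neuro = _coverage(neuro, chrom, int(s), e) > 0.5
            mgi = in_neuro and rng.random() < spec.mgi_within_neuro
            kegg = in_neuro and rng.random() < spec.kegg_within_neuro
            if rng.random() < spec.rate_missing:
                dN = dS = dNdS = None
            else:
                dS = float(rng.lognormal(np.log(0.22), 0.5))
                ratio = float(rng.lognormal(np.log(0.25), 0.6))
                dN = dS * ratio
                dNdS = dN / dS
            expr = (
                None
                if rng.random() < spec.expr_missing
                else float(rng.lognormal(np.log(0.3), 0.4))
            )
            genes.append(
                GeneRecord(
                    gene_id=f"g{gi:05d}", chrom=chrom, start=int(s), end=e,
                    dN=dN, dS=dS, dNdS=dNdS, expr_sd=expr,
                    mgi_nervous=mgi, kegg_neuro=kegg,
                )
            )
            gi += 1
    return SynthGenome(
        spec=spec,
        chrom_lengths=chrom_lengths,
        tracks=tracks,
        genes=GeneIndex(genes),
        patches=patches,
        neuro_regions=neuro,
    )


# ---------------------------------------------------------------------------
# CNV generation
# ---------------------------------------------------------------------------

def _placement_weight(genome: SynthGenome, cspec: SynthClassSpec, chrom: str, s: int, e: int) -> float:
    w = 1.0
    for track, mult in cspec.multipliers.items():
        w *= mult ** _coverage(genome.patches[track], chrom, s, e)
    w *= cspec.gene_multiplier ** _coverage(genome.patches["gene"], chrom, s, e)
    return w


def generate_cnv_set(
    class_label: str,
    n: int,
    genome: SynthGenome,
    class_spec: SynthClassSpec | None = None,
    seed: int = 0,
    max_tries: int = 500,
) -> list[CnvRecord]:
    """Draw ``n`` CNVs of one class.

    Lengths come from the class log-normal; placement is rejection-
    sampled with per-track hotspot multipliers, and each CNV is
    additionally constrained to contain (or not contain) a nervous-
    system-phenotype gene so the realised MGI-positive fraction tracks
    ``mgi_target``.  Probe counts emulate a dense SNP array (one target
    per ~2 kb).
    """
    if class_label not in ("mr", "benign"):
        raise ValueError("class_label must be 'mr' or 'benign'")
    cspec = class_spec or DEFAULT_CLASS_SPECS[class_label]
    rng = np.random.default_rng(seed)
    chroms = list(genome.chrom_lengths)
    lengths_avail = np.array([genome.chrom_lengths[c] for c in chroms], dtype=np.int64)
    longest = int(lengths_avail.max())
    w_max = 1.0
    for m in cspec.multipliers.values():
        w_max *= max(m, 1.0)
    w_max *= max(cspec.gene_multiplier, 1.0)

    records: list[CnvRecord] = []
    for i in range(n):
        length = int(rng.lognormal(np.log(cspec.length_median_bp), cspec.length_sigma))
        length = max(length, cspec.min_length_bp)
        if length >= longest:
            length = int(0.8 * longest)
        want_mgi = rng.random() < cspec.mgi_target
        placeable = lengths_avail - length + 1
        if (placeable <= 0).all():
            raise ValueError(f"CNV {class_label}_{i} of length {length} fits no chromosome")
        probs = np.maximum(placeable, 0).astype(float)
        probs /= probs.sum()
        chosen: tuple[str, int] | None = None
        fallback: tuple[str, int] | None = None
        for _ in range(max_tries):
            ci = int(rng.choice(len(chroms), p=probs))
            chrom = chroms[ci]
            start = int(rng.integers(0, placeable[ci]))
            w = _placement_weight(genome, cspec, chrom, start, start + length)
            if rng.random() >= w / w_max:
                continue
            fallback = (chrom, start)
            has_mgi = any(
                g.mgi_nervous for g in genome.genes.overlapping(chrom, start, start + length)
            )
            if has_mgi == want_mgi:
                chosen = (chrom, start)
                break
        if chosen is None:
            chosen = fallback or (chroms[int(rng.choice(len(chroms), p=probs))], 0)
        chrom, start = chosen
        records.append(
            CnvRecord(
                chrom=chrom,
                start=start,
                end=start + length,
                cnv_type="loss" if rng.random() < cspec.loss_fraction else "gain",
                probe_count=int(1 + rng.poisson(length / 2_000)),
                class_label=class_label,
                inheritance="de_novo" if class_label == "mr" else "inherited",
                cnv_id=f"{class_label}_{i}",
            )
        )
    return records


# ---------------------------------------------------------------------------
# Whole-dataset convenience
# ---------------------------------------------------------------------------

def generate_labeled_dataset(
    n_mr: int,
    n_benign: int,
    seed: int = 0,
    genome_spec: SynthGenomeSpec | None = None,
    class_specs: Mapping[str, SynthClassSpec] | None = None,
    out_dir: str | Path | None = None,
) -> tuple[SynthGenome, list[CnvRecord], list[str]]:
    """Generate a genome plus a labelled CNV set; optionally write every
    input file the annotation layer reads (BED3 tracks, tab-separated CNV
    and gene tables, and a key/value manifest recording specs and seed).
    """
    specs = dict(DEFAULT_CLASS_SPECS)
    if class_specs:
        specs.update(class_specs)
    ss = np.random.SeedSequence(seed)
    genome_seed, mr_seed, benign_seed = (int(s) for s in ss.generate_state(3) % (2**31))
    genome = generate_genome(genome_spec or SynthGenomeSpec(), seed=genome_seed)
    cnvs = generate_cnv_set("mr", n_mr, genome, specs["mr"], seed=mr_seed)
    cnvs += generate_cnv_set("benign", n_benign, genome, specs["benign"], seed=benign_seed)
    labels = [c.class_label or "unknown" for c in cnvs]
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, track in genome.tracks.items():
            track.to_bed(out / f"{name.lower()}.bed")
        write_gene_table(genome.genes.genes, out / "genes.tsv")
        write_cnv_table(cnvs, out / "cnvs.tsv")
        with open(out / "manifest.txt", "w") as fh:
            fh.write(f"seed\t{seed}\n")
            fh.write(f"n_mr\t{n_mr}\n")
            fh.write(f"n_benign\t{n_benign}\n")
            for chrom, length in genome.chrom_lengths.items():
                fh.write(f"chrom_length\t{chrom}\t{length}\n")
            fh.write(f"genome_spec\t{json.dumps(asdict(genome.spec))}\n")
            for label in ("mr", "benign"):
                fh.write(f"class_spec_{label}\t{json.dumps(asdict(specs[label]))}\n")
    return genome, cnvs, labels


def synthetic_feature_matrix(
    n_mr: int,
    n_benign: int,
    seed: int = 0,
    genome: SynthGenome | None = None,
    class_specs: Mapping[str, SynthClassSpec] | None = None,
) -> tuple[pd.DataFrame, np.ndarray, SynthGenome]:
    """Generate (or reuse) a genome, draw labelled CNVs and annotate them.

    Returns the candidate feature matrix (without the label column), the
    aligned label array, and the genome.  The main entry point for the
    training-design experiments and tests.
    """
    specs = dict(DEFAULT_CLASS_SPECS)
    if class_specs:
        specs.update(class_specs)
    ss = np.random.SeedSequence(seed)
    genome_seed, mr_seed, benign_seed = (int(s) for s in ss.generate_state(3) % (2**31))
    if genome is None:
        genome = generate_genome(SynthGenomeSpec(), seed=genome_seed)
    cnvs = generate_cnv_set("mr", n_mr, genome, specs["mr"], seed=mr_seed)
    cnvs += generate_cnv_set("benign", n_benign, genome, specs["benign"], seed=benign_seed)
    df = build_feature_matrix(cnvs, genome.tracks, genome.genes)
    y = df.pop("class_label").to_numpy()
    return df, y, genome
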