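"""Synthetic genomes, annotations, peak sets, alignments and trajectories.

Every generator is deterministic under the config seed and emits its
ground truth alongside the data, so downstream tests consume truth rather
than re-deriving it.  Reads are emitted as alignment records (hit
structure), not sequences: the aligner is upstream of this pipeline.

Statistical structure emulated:
 * a focal element family plus background families, placed without overlap;
 * peaks planted within a window of a configurable fraction of focal
   elements (association mode) or uniformly within [0, D] downstream of
   each focal TSS (TF mode), the rest uniform over the genome;
 * an 80:20 unique:multiread split, multiread hit lists sampling sister
   copies of the focal family;
 * optional spanning-gene transcription over some elements to create
   unspecific (read-through) signal;
 * geometric per-stage decay series with a flat housekeeping normalizer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from ervkit.core_io import (
    ChromSizes,
    GenomicInterval,
    MarkerPeakSet,
    ProvirusRecord,
    REGION_ORDER,
)
from ervkit.expression_analysis import StageSeries

# proportional internal splits for focal-element region maps
REGION_FRACTIONS = {
    "5LTR": 0.10, "gag": 0.25, "pro": 0.15,
    "pol": 0.25, "env": 0.15, "3LTR": 0.10,
}

STAGES = ("N0", "N1", "N2", "N3")

DEFAULT_DECAY = {
    "focal": 0.45, "NANOG": 0.50, "OCT4": 0.55, "SOX2": 0.92, "BRD2": 1.0,
}


@dataclass
class SimulationConfig:
    seed: int = 0
    chrom_sizes: Dict[str, int] = field(
        default_factory=lambda: {"chr1": 30_000_000, "chr2": 20_000_000})
    # annotation
    focal_family: str = "ERVF"
    n_focal: int = 50
    focal_length_range: Tuple[int, int] = (4_000, 6_000)
    background_families: Dict[str, int] = field(
        default_factory=lambda: {"LINE": 50, "SINE": 50})
    background_length_range: Tuple[int, int] = (500, 3_000)
    min_separation: int = 25_000
    # peaks
    assoc_fraction: float = 0.8
    assoc_window: int = 2_000
    n_background_peaks: int = 200
    tf_window: int = 500          # D of the uniform TF placement model
    # alignments
    n_reads: int = 50_000
    read_length: int = 50
    unique_fraction: float = 0.8
    max_sisters: int = 4
    expression_sigma: float = 0.8   # lognormal spread of focal expression
    background_expression: float = 0.0  # relative weight per background element
    gene_embedded_fraction: float = 0.0
    gene_extent: int = 10_000
    gene_read_density: float = 1.0  # gene reads per element read, over the span
    # trajectories
    decay_rates: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DECAY))
    trajectory_noise: float = 0.0

    def __post_init__(self) -> None:
        for name, value in (("assoc_fraction", self.assoc_fraction),
                            ("unique_fraction", self.unique_fraction),
                            ("gene_embedded_fraction", self.gene_embedded_fraction)):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_focal < 0 or self.n_reads < 0:
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("focal_length_range", "background_length_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        raw["focal_length_range"] = list(self.focal_length_range)
        raw["background_length_range"] = list(self.background_length_range)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def _region_map(iv: GenomicInterval) -> Dict[str, GenomicInterval]:
    """Proportional 5LTR..3LTR split, laid out 5'->3' along the strand."""
    length = iv.length
    order = REGION_ORDER if iv.strand != "-" else tuple(reversed(REGION_ORDER))
    bounds = np.cumsum([0.0] + [REGION_FRACTIONS[r] for r in order])
    regions: Dict[str, GenomicInterval] = {}
    for i, label in enumerate(order):
        s = iv.start + int(round(bounds[i] * length))
        e = iv.start + int(round(bounds[i + 1] * length))
        if e > s:
            regions[label] = GenomicInterval(iv.chrom, s, e, iv.strand)
    return regions


def _place_on_chrom(chrom: str, chrom_len: int, lengths: Sequence[int],
                    min_sep: int, rng: np.random.Generator) -> List[int]:
    """Uniform non-overlapping starts with a minimum gap, via the
    reduced-coordinate construction (exact, no rejection loop)."""
    n = len(lengths)
    if n == 0:
        return []
    occupied = int(sum(lengths)) + (n - 1) * min_sep
    free = chrom_len - occupied - 2 * min_sep
    if free <= 0:
        raise ValueError(
            f"{chrom} ({chrom_len} bp) too small for {n} elements with "
            f"separation {min_sep}")
    offsets = np.sort(rng.integers(0, free, size=n))
    starts = []
    cursor = min_sep
    for i, (off, length) in enumerate(zip(offsets, lengths)):
        starts.append(int(off) + cursor)
        cursor += int(length) + min_sep
    return starts


def simulate_annotation(config: SimulationConfig,
                        rng: Optional[np.random.Generator] = None
                        ) -> Tuple[ChromSizes, List[ProvirusRecord]]:
    """Place focal and background elements uniformly without overlap.

    Focal elements carry region maps and random strands; elements keep at
    least `min_separation` bp between each other so flanking contexts stay
    private.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sizes = ChromSizes(config.chrom_sizes)
    specs: List[Tuple[str, str, int]] = []   # (family, kind, length)
    lo, hi = config.focal_length_range
    for i in range(config.n_focal):
        specs.append((config.focal_family, "focal", int(rng.integers(lo, hi + 1))))
    blo, bhi = config.background_length_range
    for family, count in config.background_families.items():
        for _ in range(count):
            specs.append((family, "background", int(rng.integers(blo, bhi + 1))))
    if not specs:
        return sizes, []
    # spread elements over chromosomes proportionally to length
    names = list(sizes)
    weights = np.array([sizes[c] for c in names], dtype=float)
    weights /= weights.sum()
    chrom_of = rng.choice(len(names), size=len(specs), p=weights)
    elements: List[ProvirusRecord] = []
    counter = 0
    for ci, chrom in enumerate(names):
        idxs = [k for k in range(len(specs)) if chrom_of[k] == ci]
        lengths = [specs[k][2] for k in idxs]
        starts = _place_on_chrom(chrom, sizes[chrom], lengths,
                                 config.min_separation, rng)
        for k, start in zip(idxs, starts):
            family, kind, length = specs[k]
            strand = "+" if rng.random() < 0.5 else "-"
            iv = GenomicInterval(chrom, start, start + length, strand)
            regions = _region_map(iv) if kind == "focal" else None
            elements.append(ProvirusRecord(
                element_id=f"{family}_{counter:05d}", family=family,
                interval=iv, regions=regions))
            counter += 1
    return sizes, elements


def focal_elements(elements: Sequence[ProvirusRecord],
                   config: SimulationConfig) -> List[ProvirusRecord]:
    return [el for el in elements if el.family == config.focal_family]


def simulate_peaks(elements: Sequence[ProvirusRecord],
                   config: SimulationConfig,
                   sizes: ChromSizes,
                   mode: str = "association",
                   marker: str = "H3K4me3", cell_type: str = "sim",
                   rng: Optional[np.random.Generator] = None
                   ) -> Tuple[MarkerPeakSet, Dict[str, object]]:
    """Plant peaks near focal elements, plus uniform background peaks.

    mode="association": a fraction `assoc_fraction` of focal elements gets
    one peak uniform within `assoc_window` of a random element edge.
    mode="tf": every focal element gets one peak uniform within
    [0, tf_window] downstream of its TSS (strand-aware).
    Returns the peak set and a truth dict with the planted element ids
    (and, in TF mode, the planted offsets).
    """
    if mode not in ("association", "tf"):
        raise ValueError(f"unknown peak mode {mode!r}")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    focal = focal_elements(elements, config)
    peaks: Dict[str, List[int]] = {c: [] for c in sizes}
    truth: Dict[str, object] = {"mode": mode, "planted": [], "offsets": {}}

    if mode == "association":
        n_plant = int(round(config.assoc_fraction * len(focal)))
        order = rng.permutation(len(focal))
        for i in order[:n_plant]:
            el = focal[i]
            offset = int(rng.integers(0, config.assoc_window + 1))
            edge_left = rng.random() < 0.5
            pos = el.interval.start - offset if edge_left \
                else el.interval.end + offset
            pos = min(max(0, pos), sizes[el.chrom] - 1)
            peaks[el.chrom].append(pos)
            truth["planted"].append(el.element_id)
    else:
        for el in focal:
            offset = int(rng.integers(0, config.tf_window + 1))
            pos = el.tss + offset if el.interval.strand != "-" else el.tss - offset
            pos = min(max(0, pos), sizes[el.chrom] - 1)
            peaks[el.chrom].append(pos)
            truth["planted"].append(el.element_id)
            truth["offsets"][el.element_id] = offset

    names = list(sizes)
    weights = np.array([sizes[c] for c in names], dtype=float)
    weights /= weights.sum()
    for ci in rng.choice(len(names), size=config.n_background_peaks, p=weights):
        chrom = names[ci]
        peaks[chrom].append(int(rng.integers(0, sizes[chrom])))
    return (MarkerPeakSet(marker=marker, cell_type=cell_type, peaks=peaks),
            truth)


def simulate_alignments(elements: Sequence[ProvirusRecord],
                        config: SimulationConfig,
                        sizes: ChromSizes,
                        rng: Optional[np.random.Generator] = None,
                        gene_embedded_ids: Optional[Sequence[str]] = None
                        ) -> Tuple[List["AlignmentRecord"], pd.DataFrame]:
    """Draw alignment records with known per-element origin counts.

    Reads are allocated per element by a multinomial over expression weight
    x length; each read is unique with probability `unique_fraction`, else
    a multiread whose hit list adds 1..max_sisters sister focal elements at
    the matching internal offset.  Spanning-gene reads (unique) are layered
    over gene-embedded elements to create unspecific transcription.

    The truth table reports, per element: origin reads, gene read-through
    with midpoint inside the element, and the implied true RPKM.
    """
    from ervkit.core_io import AlignmentRecord

    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    read_len = config.read_length
    focal = focal_elements(elements, config)
    if gene_embedded_ids is None and config.gene_embedded_fraction > 0:
        n_embed = int(round(config.gene_embedded_fraction * len(focal)))
        order = rng.permutation(len(focal))
        gene_embedded_ids = [focal[i].element_id for i in order[:n_embed]]
    embedded = set(gene_embedded_ids or [])

    weights = []
    for el in elements:
        if el.family == config.focal_family:
            w = float(rng.lognormal(0.0, config.expression_sigma))
        else:
            w = config.background_expression
        weights.append(w * el.interval.length)
    weights = np.asarray(weights)
    # embedded elements are transcribed only via the spanning gene: their
    # own weight moves to the gene layer below
    embedded_weight = np.where(
        [el.element_id in embedded for el in elements], weights, 0.0)
    own_weights = weights - embedded_weight
    if weights.sum() <= 0:
        raise ValueError("no expressed element: all weights are zero")
    expected_reads = config.n_reads * weights / weights.sum()
    if own_weights.sum() > 0:
        counts = rng.multinomial(config.n_reads,
                                 own_weights / own_weights.sum())
    else:
        counts = np.zeros(len(elements), dtype=int)

    focal_idx = [i for i, el in enumerate(elements)
                 if el.family == config.focal_family]
    records: List[AlignmentRecord] = []
    rid = 0
    for i, el in enumerate(elements):
        iv = el.interval
        span = max(1, iv.length - read_len)
        for _ in range(int(counts[i])):
            offset = int(rng.integers(0, span))
            hits = [GenomicInterval(iv.chrom, iv.start + offset,
                                    min(iv.end, iv.start + offset + read_len))]
            is_multi = (el.family == config.focal_family
                        and len(focal_idx) > 1
                        and rng.random() >= config.unique_fraction)
            if is_multi:
                n_sis = int(rng.integers(1, config.max_sisters + 1))
                others = [j for j in focal_idx if j != i]
                pick = rng.choice(len(others),
                                  size=min(n_sis, len(others)), replace=False)
                for j in (others[p] for p in pick):
                    siv = elements[j].interval
                    soff = min(offset, max(0, siv.length - read_len))
                    hits.append(GenomicInterval(
                        siv.chrom, siv.start + soff,
                        min(siv.end, siv.start + soff + read_len)))
            records.append(AlignmentRecord(read_id=f"r{rid}", hits=hits))
            rid += 1

    gene_in_element = np.zeros(len(elements))
    id_to_idx = {el.element_id: i for i, el in enumerate(elements)}
    for eid in embedded:
        i = id_to_idx[eid]
        iv = elements[i].interval
        gs = max(0, iv.start - config.gene_extent)
        ge = min(sizes[iv.chrom], iv.end + config.gene_extent)
        span = ge - gs
        # uniform gene transcription at the density the element would have
        # had if independently expressed
        n_gene = int(round(config.gene_read_density * expected_reads[i]
                           * span / max(1, iv.length)))
        for _ in range(n_gene):
            offset = int(rng.integers(0, max(1, span - read_len)))
            hit = GenomicInterval(iv.chrom, gs + offset,
                                  min(ge, gs + offset + read_len))
            records.append(AlignmentRecord(read_id=f"g{rid}", hits=[hit]))
            rid += 1
            if iv.contains(hit.midpoint):
                gene_in_element[i] += 1

    n_total = len(records)
    truth = pd.DataFrame({
        "element_id": [el.element_id for el in elements],
        "family": [el.family for el in elements],
        "length_kb": [el.interval.length / 1e3 for el in elements],
        "origin_reads": counts.astype(int),
        "gene_reads_in_element": gene_in_element.astype(int),
        "gene_embedded": [el.element_id in embedded for el in elements],
    })
    truth["total_reads"] = truth["origin_reads"] + truth["gene_reads_in_element"]
    truth["true_rpkm"] = (1.0e6 * truth["total_reads"]
                          / (truth["length_kb"] * n_total))
    return records, truth


def simulate_transcript_reads(element: ProvirusRecord,
                              region_labels: Sequence[str],
                              n_reads: int,
                              rng: np.random.Generator,
                              read_length: int = 50) -> List["AlignmentRecord"]:
    """Unique reads drawn uniformly from a transcript covering only the
    given internal regions (e.g. 5LTR-gag-pro-3LTR, skipping pol/env)."""
    from ervkit.core_io import AlignmentRecord

    if not element.regions:
        raise ValueError("element has no region map")
    pieces = [element.regions[r] for r in region_labels]
    lengths = np.array([p.length for p in pieces], dtype=float)
    records: List[AlignmentRecord] = []
    for i in range(n_reads):
        piece = pieces[int(rng.choice(len(pieces), p=lengths / lengths.sum()))]
        span = max(1, piece.length - read_length)
        offset = int(rng.integers(0, span))
        start = piece.start + offset
        records.append(AlignmentRecord(
            read_id=f"t{i}",
            hits=[GenomicInterval(piece.chrom, start,
                                  min(piece.end, start + read_length))]))
    return records


def simulate_differentiation(config: SimulationConfig,
                             rng: Optional[np.random.Generator] = None
                             ) -> Dict[str, StageSeries]:
    """Geometric decay series over the stages, normalized by a flat
    housekeeping ("BRD2") series."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    norm_rate = config.decay_rates.get("BRD2", 1.0)
    normalizer = np.array([norm_rate ** t for t in range(len(STAGES))])
    out: Dict[str, StageSeries] = {}
    for name, rate in config.decay_rates.items():
        values = np.array([rate ** t for t in range(len(STAGES))])
        if config.trajectory_noise > 0:
            values = values * np.exp(
                rng.normal(0.0, config.trajectory_noise, size=len(values)))
        out[name] = StageSeries(stages=list(STAGES), values=values,
                                normalizer=normalizer.copy())
    return out


def write_fixture_dir(config: SimulationConfig, outdir,
                      peak_mode: str = "association") -> Dict[str, str]:
    """Run all generators and write plain-text fixtures to a directory.

    Emits chrom.sizes, elements (.out and .bed), region map BED, peaks
    (narrowPeak), alignments (tabular), truth tables (TSV), and the config
    (YAML).  Returns the path map.
    """
    from pathlib import Path

    from ervkit import core_io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    sizes, elements = simulate_annotation(config, rng)
    peaks, peak_truth = simulate_peaks(elements, config, sizes,
                                       mode=peak_mode, rng=rng)
    records, truth = simulate_alignments(elements, config, sizes, rng=rng)

    paths = {
        "config": str(outdir / "sim.yaml"),
        "chrom_sizes": str(outdir / "chrom.sizes"),
        "elements_out": str(outdir / "elements.out"),
        "elements_bed": str(outdir / "elements.bed"),
        "regions_bed": str(outdir / "regions.bed"),
        "peaks": str(outdir / "peaks.narrowPeak"),
        "alignments": str(outdir / "alignments.tsv"),
        "truth": str(outdir / "truth_expression.tsv"),
        "peak_truth": str(outdir / "truth_peaks.tsv"),
    }
    config.to_yaml(paths["config"])
    sizes.to_file(paths["chrom_sizes"])
    core_io.write_repeatmasker_out(elements, paths["elements_out"])
    core_io.write_bed([el.interval for el in elements], paths["elements_bed"],
                      names=[el.element_id for el in elements])
    with open(paths["regions_bed"], "w") as fh:
        for el in elements:
            if not el.regions:
                continue
            for label, sub in el.regions.items():
                fh.write(f"{sub.chrom}\t{sub.start}\t{sub.end}\t"
                         f"{el.element_id}:{label}\t0\t{sub.strand}\n")
    core_io.write_narrowpeak(peaks, paths["peaks"])
    core_io.write_alignments_tab(records, paths["alignments"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    pd.DataFrame({"element_id": peak_truth["planted"]}).to_csv(
        paths["peak_truth"], sep="\t", index=False)
    return paths
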