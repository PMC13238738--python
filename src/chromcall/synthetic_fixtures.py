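"""Self-contained synthetic datasets with known ground truth.

Generates a toy genome (chrom.sizes), fixed-width promoter-like windows,
an optional blacklist, sorted+indexed alignment files for an experiment
and an optional matched control, a truth table, and an optional
expression table correlated with enrichment.

The data model mirrors region-based chromatin profiling: background
fragments are placed uniformly at a stated expected rate per window-width
tile; each enriched window receives extra fragments so its expected
midpoint count is fold x background; coverage-distortion intervals
(emulating copy-number gain) multiply the background rate of BOTH the
experiment and the control, while enrichment affects the experiment only.
An optional gamma-mixed background makes tile counts genuinely Negative
Binomial so dispersion recovery is testable; plain mode gives Poisson.
All randomness flows from a single seed recorded in the manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam
import yaml

from .genome_io import GenomicInterval, RegionSet, write_regions_bed

logger = logging.getLogger(__name__)

__all__ = ["SimulationSpec", "simulate_dataset", "make_toy_promoters",
           "simulate_midpoints"]


@dataclass
class SimulationSpec:
    """Parameters of a synthetic chromatin-profiling dataset.

    background_rate is the expected number of fragment midpoints per
    width-W tile; enriched maps region index -> fold change (>= 1);
    distortion maps (chrom, start, end) -> multiplier applied to the
    background of both tracks.  gamma_theta, when set, gamma-mixes the
    per-tile background rate (mean preserved) so tile counts follow a
    Negative Binomial with that size parameter.
    """

    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000}
    )
    width: int = 2000
    n_regions: int = 500
    enriched: dict[int, float] = field(default_factory=dict)
    background_rate: float = 20.0
    distortion: list[tuple[str, int, int, float]] = field(default_factory=list)
    blacklist: list[tuple[str, int, int]] = field(default_factory=list)
    fragment_length_mean: float = 200.0
    fragment_length_sd: float = 30.0
    read_length: int = 50
    paired: bool = True
    with_control: bool = True
    with_expression: bool = False
    gamma_theta: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_rate <= 0:
            raise ValueError("background_rate must be positive")
        if self.width <= 0 or self.n_regions <= 0:
            raise ValueError("width and n_regions must be positive")
        for idx, fold in self.enriched.items():
            if not (0 <= idx < self.n_regions):
                raise ValueError(f"enriched index {idx} out of range")
            if fold < 1:
                raise ValueError(f"fold change {fold} must be >= 1")
        for _, _, _, mult in self.distortion:
            if mult <= 0:
                raise ValueError("distortion multiplier must be positive")
        if self.gamma_theta is not None and self.gamma_theta <= 0:
            raise ValueError("gamma_theta must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationSpec":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "enriched" in raw:
            raw["enriched"] = {int(k): float(v) for k, v in raw["enriched"].items()}
        if "distortion" in raw:
            raw["distortion"] = [tuple(d) for d in raw["distortion"]]
        if "blacklist" in raw:
            raw["blacklist"] = [tuple(b) for b in raw["blacklist"]]
        return cls(**raw)


def make_toy_promoters(
    sizes: dict[str, int], width: int, n: int, seed: int = 0
) -> RegionSet:
    """n non-overlapping width-W windows with gene-like names GENE0001...

    Windows are drawn without replacement from the W-grid of each
    chromosome, then sorted genomically, so they are disjoint by
    construction and deterministic under the seed.
    """
    candidates: list[tuple[int, int]] = []  # (chrom index, start)
    chroms = list(sizes)
    for ci, chrom in enumerate(chroms):
        for start in range(0, sizes[chrom] - width + 1, width):
            candidates.append((ci, start))
    if n > len(candidates):
        raise ValueError(
            f"cannot place {n} non-overlapping windows of width {width}: "
            f"only {len(candidates)} grid slots available"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=n, replace=False)
    picked = sorted(candidates[i] for i in chosen)
    regions = [
        GenomicInterval(chroms[ci], start, start + width) for ci, start in picked
    ]
    names = [f"GENE{k + 1:04d}" for k in range(n)]
    return RegionSet(regions=regions, names=names, width=width)


def _tile_multiplier(
    chrom: str, start: int, end: int,
    distortion: list[tuple[str, int, int, float]],
) -> float:
    mult = 1.0
    for dchrom, dstart, dend, dmult in distortion:
        if dchrom == chrom and start < dend and dstart < end:
            mult *= dmult
    return mult


def simulate_midpoints(
    spec: SimulationSpec,
    rng: np.random.Generator,
    regions: RegionSet,
    is_control: bool,
) -> dict[str, np.ndarray]:
    """Draw fragment-midpoint positions for one track.

    Per width-W tile: count ~ Poisson(rate) with rate = background_rate
    x optional gamma mixing x distortion multiplier, midpoints uniform in
    the tile.  Enriched regions (experiment only) get Poisson extra
    midpoints with mean (fold - 1) x local background rate, uniform in
    the region.
    """
    out: dict[str, list[np.ndarray]] = {}
    w = spec.width
    for chrom, length in spec.chrom_sizes.items():
        mids: list[np.ndarray] = []
        for start in range(0, length, w):
            end = min(start + w, length)
            rate = spec.background_rate * (end - start) / w
            if spec.gamma_theta is not None:
                rate *= rng.gamma(spec.gamma_theta, 1.0 / spec.gamma_theta)
            rate *= _tile_multiplier(chrom, start, end, spec.distortion)
            k = rng.poisson(rate)
            if k:
                mids.append(rng.integers(start, end, size=k))
        out[chrom] = mids
    if not is_control:
        for idx, fold in spec.enriched.items():
            iv = regions.regions[idx]
            local = spec.background_rate * _tile_multiplier(
                iv.chrom, iv.start, iv.end, spec.distortion
            )
            k = rng.poisson((fold - 1.0) * local)
            if k:
                out[iv.chrom].append(rng.integers(iv.start, iv.end, size=k))
    return {
        chrom: (
            np.sort(np.concatenate(chunks))
            if chunks
            else np.empty(0, dtype=np.int64)
        )
        for chrom, chunks in out.items()
    }


def _write_alignments(
    midpoints: dict[str, np.ndarray],
    spec: SimulationSpec,
    rng: np.random.Generator,
    out_bam: Path,
) -> int:
    """Write synthetic proper-pair (or single-end) records for each midpoint.

    No sequence content is emitted; only coordinates and flags matter to
    the caller.  MAPQ is fixed at 60.  The file is coordinate-sorted and
    indexed.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": chrom, "LN": length}
            for chrom, length in spec.chrom_sizes.items()
        ],
    }
    tid = {chrom: i for i, chrom in enumerate(spec.chrom_sizes)}
    rl = spec.read_length
    n_written = 0
    tmp = out_bam.with_suffix(".unsorted.bam")
    with pysam.AlignmentFile(str(tmp), "wb", header=header) as bam:
        for chrom, mids in midpoints.items():
            length = spec.chrom_sizes[chrom]
            if len(mids) == 0:
                continue
            frag_len = np.maximum(
                rng.normal(
                    spec.fragment_length_mean, spec.fragment_length_sd,
                    size=len(mids),
                ).round().astype(int),
                rl,
            )
            for j, (c, L) in enumerate(zip(mids, frag_len)):
                L = int(min(L, length))
                # clamp the midpoint so the fragment fits; midpoint is
                # preserved except within L/2 of a chromosome edge
                c = int(min(max(c, L // 2), length - (L - L // 2)))
                start = c - L // 2
                name = f"frag:{chrom}:{n_written}"
                if spec.paired:
                    r1 = pysam.AlignedSegment()
                    r1.query_name = name
                    r1.reference_id = tid[chrom]
                    r1.reference_start = start
                    r1.cigarstring = f"{rl}M"
                    r1.mapping_quality = 60
                    r1.flag = 0x1 | 0x2 | 0x40 | 0x20  # paired, proper, read1, mate rev
                    r1.next_reference_id = tid[chrom]
                    r1.next_reference_start = start + L - rl
                    r1.template_length = L
                    r2 = pysam.AlignedSegment()
                    r2.query_name = name
                    r2.reference_id = tid[chrom]
                    r2.reference_start = start + L - rl
                    r2.cigarstring = f"{rl}M"
                    r2.mapping_quality = 60
                    r2.flag = 0x1 | 0x2 | 0x80 | 0x10  # paired, proper, read2, rev
                    r2.next_reference_id = tid[chrom]
                    r2.next_reference_start = start
                    r2.template_length = -L
                    bam.write(r1)
                    bam.write(r2)
                else:
                    # single-end: the read's own span is the fragment, so
                    # span rl around the midpoint
                    r = pysam.AlignedSegment()
                    r.query_name = name
                    r.reference_id = tid[chrom]
                    r.reference_start = int(
                        min(max(c - rl // 2, 0), length - rl)
                    )
                    r.cigarstring = f"{rl}M"
                    r.mapping_quality = 60
                    r.flag = 0
                    bam.write(r)
                n_written += 1
    pysam.sort("-o", str(out_bam), str(tmp))
    tmp.unlink()
    pysam.index(str(out_bam))
    return n_written


def simulate_dataset(spec: SimulationSpec, outdir: str | Path) -> dict:
    """Write a complete synthetic dataset and return its manifest.

    Files: chrom.sizes, regions.bed, optional blacklist.bed, experiment
    BAM (+.bai), optional control BAM (+.bai), truth.tsv (region ->
    enriched?/fold), optional expression.tsv, manifest.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    sizes_path = outdir / "chrom.sizes"
    with open(sizes_path, "w") as fh:
        for chrom, length in spec.chrom_sizes.items():
            fh.write(f"{chrom}\t{length}\n")

    regions = make_toy_promoters(
        spec.chrom_sizes, spec.width, spec.n_regions,
        seed=int(rng.integers(2**31)),
    )
    regions_path = outdir / "regions.bed"
    write_regions_bed(regions, regions_path)

    manifest: dict = {
        "spec": {
            k: (dict(v) if isinstance(v, dict) else v)
            for k, v in dataclasses.asdict(spec).items()
        },
        "seed": spec.seed,
        "files": {
            "chrom_sizes": str(sizes_path),
            "regions": str(regions_path),
        },
    }

    if spec.blacklist:
        bl_path = outdir / "blacklist.bed"
        with open(bl_path, "w") as fh:
            for chrom, start, end in spec.blacklist:
                fh.write(f"{chrom}\t{start}\t{end}\n")
        manifest["files"]["blacklist"] = str(bl_path)

    exp_mids = simulate_midpoints(spec, rng, regions, is_control=False)
    exp_bam = outdir / "experiment.bam"
    n_exp = _write_alignments(exp_mids, spec, rng, exp_bam)
    manifest["files"]["experiment"] = str(exp_bam)
    manifest["n_experiment_fragments"] = n_exp

    if spec.with_control:
        ctrl_mids = simulate_midpoints(spec, rng, regions, is_control=True)
        ctrl_bam = outdir / "control.bam"
        n_ctrl = _write_alignments(ctrl_mids, spec, rng, ctrl_bam)
        manifest["files"]["control"] = str(ctrl_bam)
        manifest["n_control_fragments"] = n_ctrl

    truth_path = outdir / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("name\tenriched\tfold\n")
        for i, name in enumerate(regions.names):
            fold = spec.enriched.get(i, 1.0)
            fh.write(f"{name}\t{int(i in spec.enriched)}\t{fold:g}\n")
    manifest["files"]["truth"] = str(truth_path)

    if spec.with_expression:
        expr_path = outdir / "expression.tsv"
        with open(expr_path, "w") as fh:
            fh.write("name\texpression\n")
            for i, name in enumerate(regions.names):
                fold = spec.enriched.get(i, 1.0)
                # enriched promoters get elevated expression plus noise
                value = rng.normal(5.0 + 2.0 * np.log2(fold), 1.0)
                fh.write(f"{name}\t{value:.4f}\n")
        manifest["files"]["expression"] = str(expr_path)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    manifest["files"]["manifest"] = str(manifest_path)
    return manifest
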