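"""Shared fixtures: tiny SAM writers and simulated datasets."""

from __future__ import annotations

from pathlib import Path

import pytest

import chromcall as cc

SAM_HEADER = "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chr1\tLN:100000\n"


def write_sam(path: Path, records: list[str], header: str = SAM_HEADER) -> Path:
    """Write a SAM file from raw record lines (tab-joined already)."""
    path.write_text(header + "".join(r + "\n" for r in records))
    return path


def proper_pair(
    name: str, chrom: str, start: int, frag_len: int, read_len: int = 50
) -> list[str]:
    """Two SAM records forming a proper pair spanning [start, start+frag_len).

    ``start`` is 0-based; SAM POS is written 1-based.
    """
    mate_start = start + frag_len - read_len
    r1 = "\t".join(
        [name, "99", chrom, str(start + 1), "60", f"{read_len}M", "=",
         str(mate_start + 1), str(frag_len), "*", "*"]
    )
    r2 = "\t".join(
        [name, "147", chrom, str(mate_start + 1), "60", f"{read_len}M", "=",
         str(start + 1), str(-frag_len), "*", "*"]
    )
    return [r1, r2]


def single_read(
    name: str, chrom: str, start: int, read_len: int, flag: int = 0,
    mapq: int = 60,
) -> str:
    return "\t".join(
        [name, str(flag), chrom, str(start + 1), str(mapq), f"{read_len}M",
         "*", "0", "0", "*", "*"]
    )


@pytest.fixture(scope="session")
def spikein_dataset(tmp_path_factory):
    """8-fold enrichment spiked into 20 of 500 windows over background 20."""
    outdir = tmp_path_factory.mktemp("spikein")
    spec = cc.SimulationSpec(
        enriched={i: 8.0 for i in range(20)}, seed=0, with_control=True
    )
    manifest = cc.simulate_dataset(spec, outdir)
    return spec, manifest


@pytest.fixture(scope="session")
def null_dataset(tmp_path_factory):
    """Uniform background, no enrichment, no control: the global null."""
    outdir = tmp_path_factory.mktemp("null")
    spec = cc.SimulationSpec(enriched={}, seed=0, with_control=False)
    manifest = cc.simulate_dataset(spec, outdir)
    return spec, manifest


def load_dataset(manifest: dict, width: int = 2000):
    """Read back a simulated dataset's geometry and tracks."""
    files = manifest["files"]
    sizes = cc.read_chrom_sizes(files["chrom_sizes"])
    regions = cc.read_regions_bed(files["regions"], width, sizes)
    blacklist = (
        cc.read_bed_intervals(files["blacklist"]) if "blacklist" in files else []
    )
    if blacklist:
        regions = cc.flag_blacklisted(regions, blacklist)
    tiling = cc.tile_genome(sizes, width, blacklist)
    exp = cc.extract_fragment_midpoints(files["experiment"])
    ctrl = (
        cc.extract_fragment_midpoints(files["control"])
        if "control" in files
        else None
    )
    return sizes, regions, tiling, exp, ctrl
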