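"""Readers and writers for the external formats the pipeline touches.

TPS-dialect landmark files (as produced by common digitizing tools), Newick
trees, CSV tables (isotopes, diet, gut, distance matrices), genotype matrices
as CSV or a minimal VCF dialect (GT-only), plus a JSON run manifest.  Every
reader has a writer and read(write(x)) is the identity on valid data
(coordinates and branch lengths to 1e-12).  Parsers never silently drop
records: whatever is skipped is logged with a count.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import GenotypeData, LandmarkSet, SpecimenRecord, DistanceMatrix
from .phylo import Phylogeny

logger = logging.getLogger(__name__)

__all__ = [
    "read_tps",
    "write_tps",
    "read_newick",
    "write_newick",
    "read_genotypes",
    "write_genotypes_csv",
    "write_vcf_minimal",
    "read_isotope_csv",
    "read_diet_csv",
    "read_gut_csv",
    "read_distance_csv",
    "write_distance_csv",
    "write_manifest",
]


def read_tps(path) -> LandmarkSet:
    """Parse a TPS-dialect landmark file into a :class:`LandmarkSet`.

    Blocks begin ``LM=k`` followed by k lines of two reals; optional ``ID=``,
    ``IMAGE=`` and ``SCALE=`` lines follow.  When SCALE is present, every
    coordinate of the block is multiplied by it.  CURVES/POINTS outline blocks
    are ignored with a warning (outlines are digitized into semilandmarks
    upstream).  LF and CRLF line endings are both accepted.
    """
    text = Path(path).read_text()
    lines = [ln.strip() for ln in text.replace("\r\n", "\n").split("\n")]
    records: list[SpecimenRecord] = []
    blocks: list[np.ndarray] = []
    scales: list[float] = []
    i = 0
    block_no = 0
    curves_warned = False
    while i < len(lines):
        line = lines[i]
        if not line:
            i += 1
            continue
        m = re.match(r"^LM\s*=\s*(\d+)$", line, re.IGNORECASE)
        if not m:
            raise ValueError(f"expected 'LM=k' at line {i + 1}, got {line!r}")
        k = int(m.group(1))
        block_no += 1
        i += 1
        coords = []
        while i < len(lines) and len(coords) < k:
            ln = lines[i]
            if not ln:
                i += 1
                continue
            parts = ln.split()
            if len(parts) != 2:
                raise ValueError(
                    f"block {block_no}: expected {k} coordinate lines, found "
                    f"{len(coords)} before {ln!r}"
                )
            try:
                coords.append([float(parts[0]), float(parts[1])])
            except ValueError as exc:
                raise ValueError(
                    f"block {block_no}: bad coordinate line {ln!r}"
                ) from exc
            i += 1
        if len(coords) < k:
            raise ValueError(
                f"block {block_no}: expected {k} coordinate lines, file ended "
                f"after {len(coords)}"
            )
        spec_id, scale = None, 1.0
        while i < len(lines):
            ln = lines[i]
            if not ln:
                i += 1
                continue
            if re.match(r"^LM\s*=", ln, re.IGNORECASE):
                break
            key, _, value = ln.partition("=")
            key = key.strip().upper()
            if key == "ID":
                spec_id = value.strip()
            elif key == "SCALE":
                scale = float(value)
            elif key in ("IMAGE", "COMMENT"):
                pass
            elif key in ("CURVES", "POINTS"):
                if not curves_warned:
                    logger.warning("ignoring CURVES/POINTS outline data in %s", path)
                    curves_warned = True
            else:
                raise ValueError(f"block {block_no}: unrecognized line {ln!r}")
            i += 1
        records.append(SpecimenRecord(specimen_id=spec_id or f"specimen_{block_no}"))
        blocks.append(np.array(coords, float))
        scales.append(scale)

    if not blocks:
        raise ValueError(f"no landmark blocks found in {path}")
    ks = {b.shape[0] for b in blocks}
    if len(ks) > 1:
        raise ValueError(f"inconsistent landmark counts across blocks: {sorted(ks)}")
    coords = np.stack([b * s for b, s in zip(blocks, scales)])
    logger.info("read %d specimens x %d landmarks from %s", *coords.shape[:2], path)
    return LandmarkSet(records=records, coords=coords)


def write_tps(data: LandmarkSet, path) -> None:
    """Write a LandmarkSet in TPS dialect (coordinates already in final units)."""
    with open(path, "w") as fh:
        for rec, config in zip(data.records, data.coords):
            fh.write(f"LM={data.n_landmarks}\n")
            for x, y in config:
                fh.write(f"{float(x)!r} {float(y)!r}\n")
            fh.write(f"ID={rec.specimen_id}\n")


def read_newick(path) -> Phylogeny:
    """Read a single rooted Newick tree with branch lengths."""
    text = Path(path).read_text().strip()
    return Phylogeny.from_newick(text)


def write_newick(tree: Phylogeny, path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


def read_genotypes(path, format: str = "csv") -> GenotypeData:
    """Read a biallelic genotype matrix as alternate-allele dosage.

    ``csv``: columns CHROM, POS then one column per sample holding 0/1/2/NA.
    ``vcf-minimal``: sites-only parsing of the GT field (0/0, 0/1, 1/1, ./.);
    non-biallelic records are skipped with a logged count.
    """
    if format == "csv":
        df = pd.read_csv(path)
        cols = list(df.columns)
        if cols[:2] != ["CHROM", "POS"]:
            raise ValueError("genotype CSV must start with CHROM,POS columns")
        samples = cols[2:]
        loci = df[["CHROM", "POS"]].rename(columns={"CHROM": "chrom", "POS": "pos"})
        geno = df[samples].to_numpy(dtype=float).T
        return GenotypeData(samples=samples, loci=loci, genotypes=geno)
    if format == "vcf-minimal":
        samples: Optional[list[str]] = None
        chroms, positions, rows = [], [], []
        skipped = 0
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n").rstrip("\r")
                if not line or line.startswith("##"):
                    continue
                if line.startswith("#CHROM"):
                    samples = line.split("\t")[9:]
                    continue
                fields = line.split("\t")
                if samples is None:
                    raise ValueError("VCF data before #CHROM header line")
                ref, alt = fields[3], fields[4]
                if "," in alt or len(ref) != 1 or len(alt) != 1:
                    skipped += 1
                    continue
                gts = []
                for entry in fields[9:]:
                    gt = entry.split(":")[0]
                    alleles = re.split(r"[/|]", gt)
                    if "." in alleles:
                        gts.append(np.nan)
                    else:
                        gts.append(float(sum(int(a) for a in alleles)))
                chroms.append(fields[0])
                positions.append(int(fields[1]))
                rows.append(gts)
        if skipped:
            logger.info("skipped %d non-biallelic VCF records", skipped)
        if samples is None:
            raise ValueError("no #CHROM header line found")
        loci = pd.DataFrame({"chrom": chroms, "pos": positions})
        geno = np.array(rows, float).T if rows else np.empty((len(samples), 0))
        return GenotypeData(samples=samples, loci=loci, genotypes=geno)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes_csv(g: GenotypeData, path) -> None:
    df = pd.DataFrame(
        {"CHROM": g.loci["chrom"], "POS": g.loci["pos"].astype(int)}
    )
    for i, sample in enumerate(g.samples):
        col = pd.array(g.genotypes[i], dtype="Int64")
        df[sample] = col
    df.to_csv(path, index=False)


def write_vcf_minimal(g: GenotypeData, path) -> None:
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples)
            + "\n"
        )
        for j in range(g.n_loci):
            gts = [
                gt_map.get(g.genotypes[i, j], "./.")
                if np.isfinite(g.genotypes[i, j])
                else "./."
                for i in range(len(g.samples))
            ]
            fh.write(
                f"{g.loci['chrom'].iloc[j]}\t{int(g.loci['pos'].iloc[j])}\t.\tA\tT\t"
                f".\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def _read_table(path, required: list[str], name: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{name} table missing columns {missing}")
    return df


def read_isotope_csv(path) -> pd.DataFrame:
    """Columns: specimen_id, species, site, d13C, d15N, cn_ratio."""
    return _read_table(
        path, ["specimen_id", "species", "site", "d13C", "d15N", "cn_ratio"], "isotope"
    )


def read_diet_csv(path) -> pd.DataFrame:
    from .diet import DIET_CATEGORIES

    return _read_table(
        path, ["specimen_id", "species", "site"] + DIET_CATEGORIES, "diet"
    )


def read_gut_csv(path) -> pd.DataFrame:
    return _read_table(
        path,
        ["specimen_id", "species", "site", "gut_length", "standard_length"],
        "gut",
    )


def read_distance_csv(path) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    return DistanceMatrix.from_dataframe(df)


def write_distance_csv(m: DistanceMatrix, path) -> None:
    m.to_dataframe().to_csv(path)


def write_manifest(path, inputs: dict, seed: Optional[int] = None) -> None:
    """JSON run manifest recording inputs, seed, and library versions."""
    import scipy

    import ecomorph

    manifest = {
        "inputs": inputs,
        "seed": seed,
        "versions": {
            "ecomorph": getattr(ecomorph, "__version__", "unknown"),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
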