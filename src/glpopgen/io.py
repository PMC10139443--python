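"""Text formats: BEAGLE-GL, VCF, BED, SFS tables, allele-count tables, windows.

All coordinates are 0-based half-open internally; VCF emission is 1-based.
Parsers raise ``ParseError`` with the offending line number.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fstats import CountTable
from .genolik import GLMatrix
from .sfs import SFS1D, SFS2D

__all__ = [
    "ParseError",
    "write_beagle", "read_beagle",
    "write_vcf", "read_vcf",
    "read_bed",
    "write_sfs1d", "read_sfs1d", "write_sfs2d", "read_sfs2d",
    "write_counts", "read_counts",
    "write_windows", "read_windows",
]


class ParseError(ValueError):
    def __init__(self, path, lineno, message):
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


_ALLELE_CODE = {"A": "0", "C": "1", "G": "2", "T": "3"}
_CODE_ALLELE = {v: k for k, v in _ALLELE_CODE.items()}


def write_beagle(glm: GLMatrix, path) -> None:
    """BEAGLE genotype-likelihood file: marker, allele1, allele2, then
    per-individual linear triples normalized to sum 1."""
    lin = glm.linear()
    lin = lin / lin.sum(axis=2, keepdims=True)
    with open(path, "w") as fh:
        header = ["marker", "allele1", "allele2"]
        for ind in glm.individuals["id"]:
            header += [str(ind)] * 3
        fh.write("\t".join(header) + "\n")
        for s in range(glm.n_sites):
            row = [
                f"{glm.sites['contig'].iloc[s]}_{glm.sites['pos'].iloc[s]}",
                _ALLELE_CODE[glm.sites["major"].iloc[s]],
                _ALLELE_CODE[glm.sites["minor"].iloc[s]],
            ]
            row += [f"{v:.6g}" for v in lin[s].ravel()]
            fh.write("\t".join(row) + "\n")


def read_beagle(path, individuals: pd.DataFrame | None = None) -> GLMatrix:
    """Read a BEAGLE-GL file back into a :class:`GLMatrix`.

    Depth information is not part of the format; cells with a flat triple
    are marked missing (depth 0), all others get depth 1.
    """
    sites_rows, gl_rows = [], []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 6 or (len(header) - 3) % 3:
            raise ParseError(path, 1, "malformed BEAGLE header")
        ids = header[3::3]
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ParseError(path, lineno,
                                 f"expected {len(header)} fields, got {len(parts)}")
            marker = parts[0]
            contig, _, pos = marker.rpartition("_")
            try:
                trip = np.array(parts[3:], dtype=float).reshape(-1, 3)
                sites_rows.append({
                    "contig": contig, "pos": int(pos),
                    "major": _CODE_ALLELE[parts[1]], "minor": _CODE_ALLELE[parts[2]],
                    "ref": _CODE_ALLELE[parts[1]],
                })
            except (ValueError, KeyError) as exc:
                raise ParseError(path, lineno, str(exc)) from exc
            gl_rows.append(trip)
    gl_lin = np.asarray(gl_rows)
    with np.errstate(divide="ignore"):
        gl = np.log10(np.clip(gl_lin, 1e-300, None))
    gl -= gl.max(axis=2, keepdims=True)
    flat = np.isclose(gl_lin, gl_lin[:, :, :1]).all(axis=2)
    depth = np.where(flat, 0, 1)
    if individuals is None:
        individuals = pd.DataFrame({"id": ids, "location": "NA", "region": "NA"})
    return GLMatrix(sites=pd.DataFrame(sites_rows), individuals=individuals,
                    gl=gl, depth=depth)


def write_vcf(path, sites: pd.DataFrame, calls: np.ndarray,
              sample_ids: list[str], contig_lengths: dict[str, int] | None = None
              ) -> None:
    """Write hard genotype calls (0/1/2 minor-allele dose, -1 missing) as VCF.

    Positions are emitted 1-based; REF is the site's reference allele and ALT
    the other observed allele.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contig_lengths:
            for c, ln in contig_lengths.items():
                fh.write(f"##contig=<ID={c},length={int(ln)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, sample_ids)) + "\n")
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
        for s in range(len(sites)):
            ref = sites["ref"].iloc[s]
            alt = sites["minor"].iloc[s] if sites["minor"].iloc[s] != ref \
                else sites["major"].iloc[s]
            # calls count minor alleles; express relative to REF
            flip = sites["major"].iloc[s] != ref
            row = [sites["contig"].iloc[s], str(int(sites["pos"].iloc[s]) + 1),
                   ".", ref, alt, ".", "PASS", ".", "GT"]
            for g in calls[s]:
                gg = g if (g < 0 or not flip) else 2 - g
                row.append(gt_map[int(gg)])
            fh.write("\t".join(row) + "\n")


def read_vcf(path) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Read a (plain-text) VCF of biallelic GT calls written by this package.

    Returns ``(sites, calls, sample_ids)`` with 0-based positions and calls
    counting ALT alleles (-1 missing).
    """
    sites_rows, call_rows, samples = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("##"):
                continue
            parts = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                samples = parts[9:]
                continue
            if len(parts) < 10:
                raise ParseError(path, lineno, "truncated VCF record")
            try:
                sites_rows.append({
                    "contig": parts[0], "pos": int(parts[1]) - 1,
                    "ref": parts[3], "alt": parts[4],
                })
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
            row = []
            for gt in parts[9:]:
                alleles = gt.replace("|", "/").split("/")
                if "." in alleles:
                    row.append(-1)
                else:
                    row.append(sum(int(a) for a in alleles))
            call_rows.append(row)
    return (pd.DataFrame(sites_rows), np.asarray(call_rows, dtype=np.int8),
            samples)


def read_bed(path) -> dict[str, np.ndarray]:
    """Read a BED (0-based half-open) into per-contig interval arrays."""
    out: dict[str, list] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ParseError(path, lineno, "BED line needs >= 3 columns")
            try:
                out.setdefault(parts[0], []).append((int(parts[1]), int(parts[2])))
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
    return {c: np.asarray(v, dtype=float) for c, v in out.items()}


def write_sfs1d(sfs: SFS1D, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#population={sfs.population}\tfolded={int(sfs.folded)}"
                 f"\ttotal={sfs.total_sites:.6f}\n")
        fh.write(" ".join(f"{v:.8g}" for v in sfs.counts) + "\n")


def read_sfs1d(path) -> SFS1D:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ParseError(path, 1, "missing SFS header line")
        meta = dict(kv.split("=") for kv in header[1:].split())
        counts = np.array(fh.readline().split(), dtype=float)
    return SFS1D(population=meta["population"], folded=bool(int(meta["folded"])),
                 counts=counts, total_sites=float(meta["total"]))


def write_sfs2d(sfs: SFS2D, path) -> None:
    with open(path, "w") as fh:
        p1, p2 = sfs.populations
        fh.write(f"#populations={p1},{p2}\tfolded={int(sfs.folded)}"
                 f"\ttotal={sfs.total_sites:.6f}\tshape={sfs.counts.shape[0]},"
                 f"{sfs.counts.shape[1]}\n")
        for row in sfs.counts:
            fh.write(" ".join(f"{v:.8g}" for v in row) + "\n")


def read_sfs2d(path) -> SFS2D:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ParseError(path, 1, "missing SFS header line")
        meta = dict(kv.split("=") for kv in header[1:].split())
        counts = np.array([line.split() for line in fh if line.strip()],
                          dtype=float)
    shape = tuple(int(x) for x in meta["shape"].split(","))
    if counts.shape != shape:
        raise ParseError(path, 2, f"matrix shape {counts.shape} != header {shape}")
    return SFS2D(populations=tuple(meta["populations"].split(",")),
                 folded=bool(int(meta["folded"])),
                 counts=counts, total_sites=float(meta["total"]))


def write_counts(table: CountTable, path) -> None:
    """Allele-count table: header of group names, per-site "a1,a2" fields."""
    with open(path, "w") as fh:
        fh.write(" ".join(table.groups) + "\n")
        for s in range(table.n_sites):
            fh.write(" ".join(
                f"{table.allele1[s, g]},{table.allele2[s, g]}"
                for g in range(len(table.groups))
            ) + "\n")


def read_counts(path) -> CountTable:
    with open(path) as fh:
        groups = fh.readline().split()
        if not groups:
            raise ParseError(path, 1, "empty count-table header")
        a1_rows, a2_rows = [], []
        for lineno, line in enumerate(fh, start=2):
            fields = line.split()
            if len(fields) != len(groups):
                raise ParseError(path, lineno,
                                 f"expected {len(groups)} fields, got {len(fields)}")
            try:
                pairs = [tuple(map(int, f.split(","))) for f in fields]
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
            if any(len(p) != 2 for p in pairs):
                raise ParseError(path, lineno, "fields must be 'a1,a2'")
            a1_rows.append([p[0] for p in pairs])
            a2_rows.append([p[1] for p in pairs])
    return CountTable(groups=groups, allele1=np.asarray(a1_rows),
                      allele2=np.asarray(a2_rows))


def write_windows(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_windows(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
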