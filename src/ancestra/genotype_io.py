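"""Genotype containers, PLINK-style text I/O, and call-rate quality control.

The universal input to the pipeline is a matrix of alternate-allele dosages
(individuals x markers, entries 0/1/2 or missing).  Two text dialects are
supported: PLINK .ped/.map pairs, and a simple TSV dosage table (rows =
individuals, header = marker ids, ``NA`` for missing).  All writers emit
UTF-8, LF-terminated files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "read_genotypes",
    "write_genotypes",
    "read_sample_map",
    "write_sample_map",
    "qc_filter",
]

MISSING = -1  # internal sentinel for a missing dosage


@dataclass
class GenotypeMatrix:
    """Individuals x markers alternate-allele dosage matrix with missingness.

    ``dosages`` is an int8 array with entries in {0, 1, 2} or ``MISSING``
    (-1).  ``marker_positions`` is an optional DataFrame with columns
    ``chrom`` and ``pos`` (1-based), indexed like ``marker_ids``.
    """

    dosages: np.ndarray
    individual_ids: list[str]
    marker_ids: list[str]
    marker_positions: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x markers)")
        n, m = self.dosages.shape
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length mismatch")
        if len(self.marker_ids) != m:
            raise ValueError("marker_ids length mismatch")
        if len(set(self.individual_ids)) != n:
            raise ValueError("duplicate individual ids")
        if len(set(self.marker_ids)) != m:
            raise ValueError("duplicate marker ids")
        vals = self.dosages
        bad = ~np.isin(vals, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be 0, 1, 2 or missing (-1)")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def dosages_float(self) -> np.ndarray:
        """Dosages as float64 with missing entries as NaN."""
        out = self.dosages.astype(np.float64)
        out[self.missing_mask] = np.nan
        return out

    def call_rates(self) -> tuple[np.ndarray, np.ndarray]:
        """(per-individual, per-marker) fraction of non-missing calls."""
        obs = ~self.missing_mask
        return obs.mean(axis=1), obs.mean(axis=0)

    def subset(self, ind_idx=None, marker_idx=None) -> "GenotypeMatrix":
        ind_idx = np.arange(self.n_individuals) if ind_idx is None else np.asarray(ind_idx)
        marker_idx = np.arange(self.n_markers) if marker_idx is None else np.asarray(marker_idx)
        pos = None
        if self.marker_positions is not None:
            pos = self.marker_positions.iloc[marker_idx].copy()
        return GenotypeMatrix(
            self.dosages[np.ix_(ind_idx, marker_idx)],
            [self.individual_ids[i] for i in ind_idx],
            [self.marker_ids[j] for j in marker_idx],
            pos,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.individual_ids == other.individual_ids
            and self.marker_ids == other.marker_ids
            and np.array_equal(self.dosages, other.dosages)
        )


# ---------------------------------------------------------------------------
# TSV dosage dialect
# ---------------------------------------------------------------------------

def _write_tsv(G: GenotypeMatrix, path: Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("individual_id\t" + "\t".join(G.marker_ids) + "\n")
        for i, iid in enumerate(G.individual_ids):
            row = ["NA" if d == MISSING else str(int(d)) for d in G.dosages[i]]
            fh.write(iid + "\t" + "\t".join(row) + "\n")


def _read_tsv(path: Path) -> GenotypeMatrix:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.strip():
            raise ValueError(f"{path}: empty file")
        cols = header.rstrip("\n").split("\t")
        marker_ids = cols[1:]
        iids: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(cols):
                raise ValueError(f"{path}: line {lineno}: expected {len(cols)} fields, got {len(parts)}")
            iids.append(parts[0])
            try:
                rows.append([MISSING if v == "NA" else int(v) for v in parts[1:]])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
        if not rows:
            raise ValueError(f"{path}: no genotype rows")
    return GenotypeMatrix(np.array(rows, dtype=np.int8), iids, marker_ids)


# ---------------------------------------------------------------------------
# PLINK-style .ped/.map text
# ---------------------------------------------------------------------------
#
# Dosage convention on read: for each diallelic marker the two observed
# alleles are sorted lexicographically and the dosage counts copies of the
# LATER allele (e.g. for A/G, dosage = number of G alleles).  '0' denotes a
# missing allele; a genotype with any missing allele is treated as missing.

def _write_ped(G: GenotypeMatrix, path: Path) -> None:
    # Dosage is emitted as counts of allele 'B' vs 'A' so that read/write
    # round-trips under the lexicographic convention.
    mappath = Path(str(path).removesuffix(".ped") + ".map")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for i, iid in enumerate(G.individual_ids):
            alleles = []
            for d in G.dosages[i]:
                if d == MISSING:
                    alleles += ["0", "0"]
                else:
                    alleles += ["B"] * int(d) + ["A"] * (2 - int(d))
            fh.write(f"FAM{i + 1} {iid} 0 0 0 -9 " + " ".join(alleles) + "\n")
    with open(mappath, "w", encoding="utf-8", newline="\n") as fh:
        for j, mid in enumerate(G.marker_ids):
            if G.marker_positions is not None:
                chrom = G.marker_positions.iloc[j]["chrom"]
                pos = int(G.marker_positions.iloc[j]["pos"])
            else:
                chrom, pos = 1, j + 1
            fh.write(f"{chrom}\t{mid}\t0\t{pos}\n")


def _read_ped(path: Path) -> GenotypeMatrix:
    mappath = Path(str(path).removesuffix(".ped") + ".map")
    markers: list[str] = []
    chroms: list[str] = []
    positions: list[int] = []
    with open(mappath, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{mappath}: line {lineno}: expected >=4 fields")
            chroms.append(parts[0])
            markers.append(parts[1])
            positions.append(int(parts[3]))
    m = len(markers)
    if m == 0:
        raise ValueError(f"{mappath}: empty map file")
    iids: list[str] = []
    allele_rows: list[list[str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f"{path}: line {lineno}: expected {6 + 2 * m} fields, got {len(parts)}"
                )
            iids.append(parts[1])
            allele_rows.append(parts[6:])
    if not iids:
        raise ValueError(f"{path}: empty file")
    n = len(iids)
    alleles = np.array(allele_rows).reshape(n, m, 2)
    dosages = np.full((n, m), MISSING, dtype=np.int8)
    for j in range(m):
        col = alleles[:, j, :]
        observed = sorted(set(col.ravel()) - {"0"})
        if len(observed) > 2:
            raise ValueError(f"{path}: marker {markers[j]} is not diallelic: {observed}")
        if not observed:
            continue
        alt = observed[-1]  # lexicographically later allele
        ok = ~np.any(col == "0", axis=1)
        dosages[ok, j] = (col[ok] == alt).sum(axis=1)
    pos = pd.DataFrame({"chrom": chroms, "pos": positions}, index=markers)
    return GenotypeMatrix(dosages, iids, markers, pos)


def read_genotypes(path, dialect: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from ``path`` in the given dialect.

    ``dialect`` is ``"ped"`` or ``"tsv"``; inferred from the extension when
    omitted.
    """
    path = Path(path)
    if dialect is None:
        dialect = "ped" if path.suffix == ".ped" else "tsv"
    if dialect == "ped":
        return _read_ped(path)
    if dialect == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_genotypes(G: GenotypeMatrix, path, dialect: str | None = None) -> None:
    path = Path(path)
    if dialect is None:
        dialect = "ped" if path.suffix == ".ped" else "tsv"
    if dialect == "ped":
        _write_ped(G, path)
    elif dialect == "tsv":
        _write_tsv(G, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Sample / annotation maps
# ---------------------------------------------------------------------------

def read_sample_map(path) -> dict[str, str]:
    """Read a 2-column TSV of (individual id, sample label)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "label"], dtype=str)
    if df["id"].duplicated().any():
        raise ValueError("duplicate ids in sample map")
    return dict(zip(df["id"], df["label"]))


def write_sample_map(mapping: Mapping[str, str], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for k, v in mapping.items():
            fh.write(f"{k}\t{v}\n")


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

def qc_filter(
    G: GenotypeMatrix,
    ind_threshold: float = 0.95,
    marker_threshold: float = 0.95,
    log=None,
) -> GenotypeMatrix:
    """Drop individuals and markers with call rates below the thresholds.

    Thresholds are exclusive: a call rate exactly equal to the threshold is
    kept (the filter removes rates strictly below it).  Markers are filtered
    first, then individuals, then markers are re-checked once.  Surviving
    dosages are never modified and nothing is imputed.
    """
    if not (0 < ind_threshold <= 1 and 0 < marker_threshold <= 1):
        raise ValueError("thresholds must lie in (0, 1]")
    out = G
    for stage in ("markers", "individuals", "markers-recheck"):
        ind_cr, marker_cr = out.call_rates()
        if stage in ("markers", "markers-recheck"):
            keep = np.where(marker_cr >= marker_threshold)[0]
            if len(keep) < out.n_markers:
                if log is not None:
                    log(f"qc: dropping {out.n_markers - len(keep)} markers ({stage})")
                out = out.subset(marker_idx=keep)
        else:
            keep = np.where(ind_cr >= ind_threshold)[0]
            if len(keep) == 0:
                raise ValueError("qc_filter removed all individuals")
            if len(keep) < out.n_individuals:
                if log is not None:
                    log(f"qc: dropping {out.n_individuals - len(keep)} individuals")
                out = out.subset(ind_idx=keep)
    if out.n_markers == 0:
        raise ValueError("qc_filter removed all markers")
    return out
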