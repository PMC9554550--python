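"""Parsing, cleaning and conversion of pooled allele read counts.

Two on-disk dialects are supported:

* ``tsv`` — explicit columns ``locus_id  ref  alt`` followed by one
  ``<accession>.ref`` / ``<accession>.alt`` column pair per accession.
* ``sync`` — the PoPoolation-style pooled format: ``chrom  pos  ref``
  followed by one ``A:T:C:G:N:del`` colon field per accession (1-based
  positions).  The alternate allele is taken as the non-reference
  nucleotide with the highest total read count; the number of distinct
  nucleotides observed is recorded so tri-/tetra-allelic loci can be
  excluded downstream.

The cleaning rules mirror a targeted pool-seq genotyping protocol:
per-cell allele counts below a threshold (default 8) are zeroed to
remove sequencing-error calls, and only polymorphic bi-allelic loci with
dataset-wide minor allele frequency >= 5% are retained.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    AccessionMetadata,
    AlleleFrequencyMatrix,
    LocusInfo,
    ReadCountMatrix,
)

_SYNC_ORDER = "ATCGN*"  # A:T:C:G:N:del


class CountsParseError(ValueError):
    """Malformed counts file; message names the offending line."""


def _default_accessions(n: int) -> list[AccessionMetadata]:
    return [AccessionMetadata(accession_id=f"pool_{i + 1}") for i in range(n)]


def parse_counts(
    path: str | Path,
    format: str = "tsv",
    accessions: Sequence[AccessionMetadata] | None = None,
) -> ReadCountMatrix:
    """Read a counts file in the ``tsv`` or ``sync`` dialect.

    Parameters
    ----------
    path
        File to read.
    format
        ``"tsv"`` or ``"sync"``.
    accessions
        Optional metadata for the pools, in file column order.  When
        omitted, placeholder metadata is synthesised (for ``tsv`` the
        accession ids come from the header).
    """
    path = Path(path)
    if format == "tsv":
        return _parse_tsv(path, accessions)
    if format == "sync":
        return _parse_sync(path, accessions)
    raise ValueError(f"unknown counts format {format!r}")


def _parse_tsv(path: Path, accessions) -> ReadCountMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["locus_id", "ref", "alt"]:
            raise CountsParseError(f"{path}:1: expected header locus_id/ref/alt")
        pair_cols = header[3:]
        if len(pair_cols) % 2:
            raise CountsParseError(f"{path}:1: odd number of count columns")
        ids = []
        for i in range(0, len(pair_cols), 2):
            a, b = pair_cols[i], pair_cols[i + 1]
            if not (a.endswith(".ref") and b.endswith(".alt") and a[:-4] == b[:-4]):
                raise CountsParseError(f"{path}:1: bad column pair {a!r}/{b!r}")
            ids.append(a[:-4])
        if accessions is None:
            accessions = [AccessionMetadata(accession_id=i) for i in ids]
        elif [a.accession_id for a in accessions] != ids:
            raise CountsParseError(f"{path}: accession metadata does not match header")

        loci, rows, seen = [], [], set()
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3 + 2 * len(ids):
                raise CountsParseError(f"{path}:{lineno}: expected "
                                       f"{3 + 2 * len(ids)} fields, got {len(fields)}")
            locus_id, ref, alt = fields[:3]
            if locus_id in seen:
                raise CountsParseError(f"{path}:{lineno}: duplicate locus_id {locus_id!r}")
            seen.add(locus_id)
            try:
                vals = [int(v) for v in fields[3:]]
            except ValueError as exc:
                raise CountsParseError(f"{path}:{lineno}: non-integer count") from exc
            loci.append(LocusInfo(locus_id=locus_id, ref_allele=ref, alt_allele=alt))
            rows.append(np.array(vals).reshape(-1, 2))
    if not loci:
        raise CountsParseError(f"{path}: no data rows")
    counts = np.stack(rows, axis=1)  # accession x locus x 2
    return ReadCountMatrix(accessions=list(accessions), loci=loci, counts=counts)


def _parse_sync(path: Path, accessions) -> ReadCountMatrix:
    loci, rows, seen = [], [], []
    n_pools = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise CountsParseError(f"{path}:{lineno}: expected chrom/pos/ref + pools")
            chrom, pos, ref = fields[0], fields[1], fields[2].upper()
            if n_pools is None:
                n_pools = len(fields) - 3
            elif len(fields) - 3 != n_pools:
                raise CountsParseError(f"{path}:{lineno}: inconsistent pool count")
            locus_id = f"{chrom}_{pos}"
            if locus_id in seen:
                raise CountsParseError(f"{path}:{lineno}: duplicate locus {locus_id!r}")
            seen.append(locus_id)

            per_pool = np.zeros((n_pools, 6), dtype=int)
            for j, col in enumerate(fields[3:]):
                parts = col.split(":")
                if len(parts) != 6:
                    raise CountsParseError(f"{path}:{lineno}: bad sync field {col!r}")
                try:
                    per_pool[j] = [int(v) for v in parts]
                except ValueError as exc:
                    raise CountsParseError(f"{path}:{lineno}: non-integer count") from exc

            totals = per_pool[:, :4].sum(axis=0)  # A,T,C,G over pools
            if ref not in _SYNC_ORDER[:4]:
                raise CountsParseError(f"{path}:{lineno}: reference base {ref!r}")
            ref_idx = _SYNC_ORDER.index(ref)
            non_ref = [i for i in range(4) if i != ref_idx]
            alt_idx = max(non_ref, key=lambda i: totals[i])
            if totals[alt_idx] == 0:  # monomorphic: pick a fixed arbitrary alt
                alt_idx = non_ref[0]
            n_obs = int(np.count_nonzero(totals))
            loci.append(LocusInfo(
                locus_id=locus_id,
                ref_allele=ref,
                alt_allele=_SYNC_ORDER[alt_idx],
                n_alleles_observed=max(n_obs, 1),
            ))
            rows.append(per_pool[:, [ref_idx, alt_idx]])
    if not loci:
        raise CountsParseError(f"{path}: no data rows")
    counts = np.stack(rows, axis=1)
    if accessions is None:
        accessions = _default_accessions(counts.shape[0])
    elif len(accessions) != counts.shape[0]:
        raise CountsParseError(f"{path}: metadata lists {len(accessions)} accessions, "
                               f"file has {counts.shape[0]} pools")
    return ReadCountMatrix(accessions=list(accessions), loci=loci, counts=counts)


def write_counts(rcm: ReadCountMatrix, path: str | Path, format: str = "tsv") -> None:
    """Write counts in the ``tsv`` or ``sync`` dialect (round-trip safe)."""
    path = Path(path)
    if format == "tsv":
        cols = ["locus_id", "ref", "alt"]
        for a in rcm.accession_ids:
            cols += [f"{a}.ref", f"{a}.alt"]
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for j, loc in enumerate(rcm.loci):
                vals = rcm.counts[:, j, :].ravel()
                fh.write("\t".join(
                    [loc.locus_id, loc.ref_allele, loc.alt_allele]
                    + [str(int(v)) for v in vals]) + "\n")
    elif format == "sync":
        with open(path, "w") as fh:
            for j, loc in enumerate(rcm.loci):
                chrom, _, pos = loc.locus_id.rpartition("_")
                if not chrom or not pos.isdigit():
                    chrom, pos = loc.locus_id, str(j + 1)
                cols = [chrom, pos, loc.ref_allele]
                ri = _SYNC_ORDER.index(loc.ref_allele.upper())
                ai = _SYNC_ORDER.index(loc.alt_allele.upper())
                for i in range(rcm.n_accessions):
                    six = [0] * 6
                    six[ri] = int(rcm.counts[i, j, 0])
                    six[ai] = int(rcm.counts[i, j, 1])
                    cols.append(":".join(str(v) for v in six))
                fh.write("\t".join(cols) + "\n")
    else:
        raise ValueError(f"unknown counts format {format!r}")


def zero_low_counts(rcm: ReadCountMatrix, min_count: int = 8) -> ReadCountMatrix:
    """Zero out per-cell allele counts below ``min_count``.

    Counts below the threshold are treated as sequencing error and set
    to zero; counts at or above it are untouched.  Idempotent.
    """
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    counts = rcm.counts.copy()
    counts[counts < min_count] = 0
    return ReadCountMatrix(accessions=rcm.accessions, loci=rcm.loci, counts=counts)


def filter_loci(
    rcm: ReadCountMatrix,
    maf_min: float = 0.05,
    biallelic_only: bool = True,
) -> tuple[ReadCountMatrix, dict]:
    """Drop non-bi-allelic, monomorphic and low-MAF loci.

    The dataset-wide minor allele frequency of a locus is the minor-side
    of the unweighted mean of per-accession alternate-allele frequencies
    over accessions with non-zero coverage (insensitive to depth
    imbalance between pools).  Returns the pruned matrix (counts of
    retained loci unchanged) and a report of loci dropped per rule.
    """
    totals = rcm.counts.sum(axis=2).astype(float)           # acc x loci
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(totals > 0, rcm.counts[:, :, 1] / np.where(totals > 0, totals, 1), np.nan)

    keep, dropped = [], {"non_biallelic": [], "monomorphic": [], "low_maf": [], "all_missing": []}
    for j, loc in enumerate(rcm.loci):
        if biallelic_only and loc.n_alleles_observed != 2:
            dropped["non_biallelic"].append(loc.locus_id)
            continue
        col = freq[:, j]
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            dropped["all_missing"].append(loc.locus_id)
            continue
        if np.all(obs == 0.0) or np.all(obs == 1.0):
            dropped["monomorphic"].append(loc.locus_id)
            continue
        mean_alt = float(obs.mean())
        if min(mean_alt, 1.0 - mean_alt) < maf_min:
            dropped["low_maf"].append(loc.locus_id)
            continue
        keep.append(j)

    if not keep:
        raise ValueError("filter_loci removed every locus")
    report = {
        "n_input": rcm.n_loci,
        "n_retained": len(keep),
        "dropped": {rule: ids for rule, ids in dropped.items()},
        "params": {"maf_min": maf_min, "biallelic_only": biallelic_only},
    }
    return rcm.select_loci(keep), report


def to_frequencies(rcm: ReadCountMatrix) -> AlleleFrequencyMatrix:
    """Convert filtered read counts to alternate-allele frequencies.

    ``freq = alt / (ref + alt)``; cells with zero total count are marked
    missing.  The haploid pool size attached to every accession is
    ``2 x pool_n_individuals`` regardless of ploidy (diploidization).
    """
    totals = rcm.counts.sum(axis=2).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = rcm.counts[:, :, 1] / totals
    missing = totals == 0
    freq[missing] = np.nan
    return AlleleFrequencyMatrix(
        accessions=rcm.accessions, loci=rcm.loci, freq=freq, missing=missing
    )


def write_frequencies(afm: AlleleFrequencyMatrix, path: str | Path) -> None:
    afm.to_frame().to_csv(path, sep="\t", index_label="accession_id", na_rep="NA")


def write_filter_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)


def read_metadata(path: str | Path) -> list[AccessionMetadata]:
    """Read accession metadata from a TSV with the AccessionMetadata fields."""
    df = pd.read_csv(path, sep="\t", dtype={"accession_id": str})
    out = []
    for _, row in df.iterrows():
        mat = row.get("maturity")
        out.append(AccessionMetadata(
            accession_id=row["accession_id"],
            origin_group=row.get("origin_group", "Synthetic"),
            type_group=row.get("type_group", "Synthetic"),
            ploidy=int(row.get("ploidy", 2)),
            pool_n_individuals=int(row.get("pool_n_individuals", 10)),
            latitude=float(row.get("latitude", 0.0)),
            longitude=float(row.get("longitude", 0.0)),
            maturity=None if pd.isna(mat) else str(mat),
        ))
    return out


def write_metadata(accessions: Sequence[AccessionMetadata], path: str | Path) -> None:
    pd.DataFrame([vars(a) for a in accessions]).to_csv(path, sep="\t", index=False)


__all__ = [
    "CountsParseError", "parse_counts", "write_counts", "zero_low_counts",
    "filter_loci", "to_frequencies", "write_frequencies",
    "write_filter_report", "read_metadata", "write_metadata",
]
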