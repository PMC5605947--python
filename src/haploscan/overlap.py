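"""Checksum-based detection of individuals duplicated across cohorts.

Cohorts that cannot share raw genotypes can still detect participant
overlap: both sides agree on a panel of shared SNPs split into batches,
hash each individual's genotype string per batch, and exchange only the
hashes.  Identical hashes across all batches identify the same genome
with negligible false-positive probability; the per-batch match count is
always reported so a looser single-batch criterion can be applied as a
sensitivity mode.

The hash is CRC-32 over a canonical byte encoding of the 0/1/2 genotype
codes (missing encoded explicitly as "M" so missingness patterns cannot
silently collide).
"""

from __future__ import annotations

import hashlib
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .qc import MISSING

N_SNPS_DEFAULT = 500
N_BATCHES_DEFAULT = 10


@dataclass
class ChecksumPanel:
    """Batch assignment of panel SNPs, shared verbatim between cohorts."""

    table: pd.DataFrame  # columns: batch chrom pos ref alt snp_index
    panel_id: str

    @property
    def n_batches(self) -> int:
        return int(self.table["batch"].max()) + 1


def _panel_id(table: pd.DataFrame) -> str:
    payload = "\n".join(
        f"{r.batch}\t{r.chrom}\t{r.pos}\t{r.ref}\t{r.alt}"
        for r in table.itertuples()
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def select_panel(
    shared_snps: pd.DataFrame,
    n_snps: int = N_SNPS_DEFAULT,
    n_batches: int = N_BATCHES_DEFAULT,
    seed: int = 0,
) -> ChecksumPanel:
    """Randomly select ``n_snps`` shared SNPs into ``n_batches`` equal batches.

    ``shared_snps`` needs columns ``chrom, pos, ref, alt`` (row order
    defines ``snp_index`` into each cohort's harmonized genotype matrix).
    Batches are equal-sized and each is sorted by chromosome + bp so the
    byte encoding is identical on both sides.  Deterministic given seed.
    """
    if n_snps % n_batches:
        raise ValueError("n_snps must be divisible by n_batches")
    if len(shared_snps) < n_snps:
        raise ValueError(
            f"only {len(shared_snps)} shared SNPs; {n_snps} requested"
        )
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(len(shared_snps), size=n_snps, replace=False))
    shuffled = rng.permutation(n_snps)
    per = n_snps // n_batches
    parts = []
    for b in range(n_batches):
        idx = chosen[shuffled[b * per:(b + 1) * per]]
        sub = shared_snps.iloc[idx].copy()
        sub["snp_index"] = idx
        sub["batch"] = b
        parts.append(sub.sort_values(["chrom", "pos"]))
    table = pd.concat(parts, ignore_index=True)[
        ["batch", "chrom", "pos", "ref", "alt", "snp_index"]
    ]
    return ChecksumPanel(table=table, panel_id=_panel_id(table))


def write_panel(panel: ChecksumPanel, path: str) -> None:
    panel.table.to_csv(path, sep="\t", index=False)


def read_panel(path: str) -> ChecksumPanel:
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return ChecksumPanel(table=table, panel_id=_panel_id(table))


@dataclass
class ChecksumProfile:
    """One individual's ordered batch checksums (None = uncomputable batch)."""

    iid: str
    checksums: tuple
    panel_id: str


def batch_checksums(
    dosages: np.ndarray, sample_ids, panel: ChecksumPanel
) -> list[ChecksumProfile]:
    """CRC-32 checksum per individual per batch.

    ``dosages`` is the cohort's ``(n, m)`` genotype matrix whose columns
    the panel's ``snp_index`` refers to; missing genotypes
    (:data:`haploscan.qc.MISSING`) are encoded as "M".  A batch whose SNPs
    are absent from the matrix entirely is flagged uncomputable (None).
    """
    dosages = np.asarray(dosages)
    code = {0: b"0", 1: b"1", 2: b"2"}
    profiles = []
    batch_cols = [
        panel.table.loc[panel.table["batch"] == b, "snp_index"].to_numpy()
        for b in range(panel.n_batches)
    ]
    for i, iid in enumerate(sample_ids):
        sums = []
        for cols in batch_cols:
            if np.any(cols >= dosages.shape[1]):
                sums.append(None)
                continue
            raw = b"".join(
                code.get(int(g), b"M") if g != MISSING else b"M"
                for g in dosages[i, cols]
            )
            sums.append(zlib.crc32(raw))
        profiles.append(
            ChecksumProfile(iid=str(iid), checksums=tuple(sums), panel_id=panel.panel_id)
        )
    return profiles


def detect_overlap(
    profiles_a: list[ChecksumProfile],
    profiles_b: list[ChecksumProfile],
    min_matching_batches: int | None = None,
) -> pd.DataFrame:
    """Candidate duplicate pairs across cohorts.

    Pairs are reported with their per-batch match count; those reaching
    ``min_matching_batches`` (default: all batches) are flagged as
    overlaps.  Requires both cohorts to have used the identical panel.
    """
    if not profiles_a or not profiles_b:
        return pd.DataFrame(columns=["iid_a", "iid_b", "n_match", "overlap"])
    pid = profiles_a[0].panel_id
    if any(p.panel_id != pid for p in profiles_a + profiles_b):
        raise ValueError("checksum profiles computed on different panels")
    n_batches = len(profiles_a[0].checksums)
    threshold = n_batches if min_matching_batches is None else min_matching_batches

    counts: dict = {}
    for b in range(n_batches):
        bucket: dict = {}
        for ia, p in enumerate(profiles_a):
            c = p.checksums[b]
            if c is not None:
                bucket.setdefault(c, []).append(ia)
        for ib, p in enumerate(profiles_b):
            c = p.checksums[b]
            if c is None:
                continue
            for ia in bucket.get(c, ()):
                counts[(ia, ib)] = counts.get((ia, ib), 0) + 1
    rows = [
        {
            "iid_a": profiles_a[ia].iid,
            "iid_b": profiles_b[ib].iid,
            "n_match": n,
            "overlap": n >= threshold,
        }
        for (ia, ib), n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["iid_a", "iid_b", "n_match", "overlap"])
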