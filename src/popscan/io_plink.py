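"""Readers and writers for PLINK text (ped/map) and binary (bed/bim/fam) sets.

The binary layout follows the PLINK 1 ``bed`` v1.00 SNP-major format:
a 3-byte magic ``6c 1b 01`` followed by ceil(n_samples/4) bytes per
marker, two bits per genotype, samples packed little-endian within each
byte. Two-bit codes: ``00`` homozygous allele_a, ``10`` heterozygous,
``11`` homozygous allele_b, ``01`` missing.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .panel import MARKER_COLUMNS, MISSING, GenotypePanel, PanelError

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# dosage (0,1,2,missing) -> 2-bit code, and back
_DOSAGE_TO_CODE = {0: 0b00, 1: 0b10, 2: 0b11, MISSING: 0b01}
_CODE_TO_DOSAGE = np.array([0, MISSING, 1, 2], dtype=np.int8)

_SEX_TO_PLINK = {"male": "1", "female": "2", "unknown": "0"}
_PLINK_TO_SEX = {"1": "male", "2": "female"}


class PlinkFormatError(PanelError):
    """Malformed PLINK file content."""


def read_panel(path_prefix: str | Path, format: str = "ped") -> GenotypePanel:
    """Read a PLINK file set ``<prefix>.ped/.map`` or ``.bed/.bim/.fam``.

    Dosages count copies of allele_b (the second allele column of the
    bim file / the second-most-frequent... no inference is done: allele_a
    and allele_b are taken verbatim from the files). ``0 0`` genotypes and
    binary code ``01`` map to missing.
    """
    prefix = Path(path_prefix)
    if format == "ped":
        return _read_ped(prefix)
    if format == "bed":
        return _read_bed(prefix)
    raise ValueError(f"format must be 'ped' or 'bed', got {format!r}")


def write_panel(panel: GenotypePanel, path_prefix: str | Path,
                format: str = "ped") -> None:
    """Write a panel as a PLINK file set readable by :func:`read_panel`."""
    if panel.n_markers == 0:
        raise PanelError("refusing to write a panel with no markers")
    if panel.n_samples == 0:
        raise PanelError("refusing to write a panel with no samples")
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if format == "ped":
        _write_ped(panel, prefix)
    elif format == "bed":
        _write_bed(panel, prefix)
    else:
        raise ValueError(f"format must be 'ped' or 'bed', got {format!r}")


# ---------------------------------------------------------------- text


def _read_map(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for k, line in enumerate(fh):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise PlinkFormatError(
                    f"{path}: line {k + 1}: expected 4 fields, got {len(parts)}")
            rows.append((parts[1], parts[0], int(parts[3])))
    return pd.DataFrame(rows, columns=["id", "chromosome", "position"])


def _read_ped(prefix: Path) -> GenotypePanel:
    markers = _read_map(prefix.with_suffix(".map"))
    m = len(markers)

    iids, pops, sexes = [], [], []
    allele_rows = []
    with open(prefix.with_suffix(".ped")) as fh:
        for k, line in enumerate(fh):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise PlinkFormatError(
                    f"{prefix.with_suffix('.ped')}: line {k + 1}: expected "
                    f"{6 + 2 * m} fields, got {len(parts)}")
            pops.append(parts[0])
            iids.append(parts[1])
            sexes.append(_PLINK_TO_SEX.get(parts[4], "unknown"))
            allele_rows.append(parts[6:])

    n = len(iids)
    alleles = np.array(allele_rows, dtype=object).reshape(n, m, 2) if n else \
        np.empty((0, m, 2), dtype=object)

    # ped files carry no allele ordering; the reader's convention is
    # deterministic: allele_a/allele_b are the distinct non-missing codes
    # in sorted order. A marker showing a single allele gets allele_b '0'.
    allele_a = np.empty(m, dtype=object)
    allele_b = np.empty(m, dtype=object)
    dosage = np.full((n, m), MISSING, dtype=np.int8)
    for j in range(m):
        col = alleles[:, j, :]
        seen = sorted({a for a in col.ravel() if a != "0"})
        if len(seen) > 2:
            raise PlinkFormatError(
                f"{prefix.with_suffix('.ped')}: marker index {j}: more than "
                f"2 alleles {seen}")
        a1 = seen[0] if seen else "0"
        a2 = seen[1] if len(seen) > 1 else "0"
        allele_a[j], allele_b[j] = a1, a2
        for i in range(n):
            x, y = col[i]
            if x == "0" or y == "0":
                continue
            d = (x == a2) + (y == a2)
            dosage[i, j] = d

    markers = markers.assign(allele_a=allele_a, allele_b=allele_b)
    samples = pd.DataFrame(
        {"individual_id": iids, "population": pops, "sex": sexes})
    return GenotypePanel(markers[MARKER_COLUMNS], samples, dosage)


def _write_ped(panel: GenotypePanel, prefix: Path) -> None:
    with open(prefix.with_suffix(".map"), "w") as fh:
        for _, r in panel.markers.iterrows():
            fh.write(f"{r.chromosome}\t{r.id}\t0\t{r.position}\n")

    a = panel.markers["allele_a"].to_numpy()
    b = panel.markers["allele_b"].to_numpy()
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, (_, s) in enumerate(panel.samples.iterrows()):
            fields = [str(s.population), str(s.individual_id), "0", "0",
                      _SEX_TO_PLINK[s.sex], "-9"]
            row = panel.dosage[i]
            for j in range(panel.n_markers):
                d = row[j]
                if d == MISSING:
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [a[j], a[j]]
                elif d == 1:
                    fields += [a[j], b[j]]
                else:
                    fields += [b[j], b[j]]
            fh.write(" ".join(fields) + "\n")


# -------------------------------------------------------------- binary


def _read_bed(prefix: Path) -> GenotypePanel:
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chromosome", "id", "cm", "position", "allele_a", "allele_b"],
        dtype={"chromosome": str, "id": str,
               "allele_a": str, "allele_b": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["population", "individual_id", "pat", "mat", "sex", "pheno"],
        dtype={"population": str, "individual_id": str, "sex": str},
    )
    fam["sex"] = fam["sex"].map(_PLINK_TO_SEX).fillna("unknown")

    n, m = len(fam), len(bim)
    bytes_per_snp = (n + 3) // 4
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise PlinkFormatError(
            f"{prefix.with_suffix('.bed')}: bad magic bytes (not a v1.00 "
            "SNP-major bed file)")
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_snp * m:
        raise PlinkFormatError(
            f"{prefix.with_suffix('.bed')}: truncated: expected "
            f"{bytes_per_snp * m} data bytes, found {body.size}")

    body = body.reshape(m, bytes_per_snp)
    # unpack 2-bit codes, little-endian within byte
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (body >> (2 * k)) & 0b11
    dosage = _CODE_TO_DOSAGE[codes[:, :n]].T  # (n, m)

    markers = bim[["id", "chromosome", "position", "allele_a", "allele_b"]]
    samples = fam[["individual_id", "population", "sex"]]
    return GenotypePanel(markers, samples, dosage)


def _write_bed(panel: GenotypePanel, prefix: Path) -> None:
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for _, r in panel.markers.iterrows():
            fh.write(f"{r.chromosome}\t{r.id}\t0\t{r.position}"
                     f"\t{r.allele_a}\t{r.allele_b}\n")
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for _, s in panel.samples.iterrows():
            fh.write(f"{s.population}\t{s.individual_id}\t0\t0"
                     f"\t{_SEX_TO_PLINK[s.sex]}\t-9\n")

    n, m = panel.n_samples, panel.n_markers
    code = np.empty((n, m), dtype=np.uint8)
    for d, c in _DOSAGE_TO_CODE.items():
        code[panel.dosage == d] = c
    bytes_per_snp = (n + 3) // 4
    padded = np.zeros((bytes_per_snp * 4, m), dtype=np.uint8)
    padded[:n] = code
    packed = np.zeros((bytes_per_snp, m), dtype=np.uint8)
    for k in range(4):
        packed |= padded[k::4] << (2 * k)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.T.tobytes())  # SNP-major
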