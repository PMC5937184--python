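"""Readers and writers for the package's on-disk formats.

* QTL meta-table: a CSV with one row per significant locus (schema in
  ``QTL_COLUMNS``), validated row-by-row with line-numbered diagnostics.
* Genotypes: plink bed/bim/fam triples (SNP-major 2-bit codes) and
  plain-text VCF; both load into :class:`~behavarch.panel.GenotypePanel`.
* Phenotypes: whitespace-delimited .phen files (family id, individual
  id, value; ``NA``/``-9`` are missing).

Positions are 1-based throughout (bim/VCF convention).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, SchemaError
from .panel import GenotypePanel

#: canonical column order of the compiled QTL table
QTL_COLUMNS = [
    "study_id",
    "species_a",
    "species_b",
    "taxon_class",
    "behavioral_category",
    "trait_name",
    "effect_size_pve",
    "lod",
    "neglog10_p",
    "sample_size",
    "generations_diverged",
    "years_diverged",
    "cross_type",
    "chrom",
    "pos",
]

_MANDATORY = [
    "study_id",
    "species_a",
    "species_b",
    "behavioral_category",
    "effect_size_pve",
    "sample_size",
    "cross_type",
]


def read_qtl_csv(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Load and validate a compiled QTL table.

    ``column_map`` renames file headers to the canonical schema (file
    name -> canonical name) for tables produced elsewhere.  Rows that
    violate the record invariants — PVE outside (0, 100], nonpositive
    sample size, a cross type inconsistent with the species pair, or no
    significance score at all — are dropped with line-numbered
    diagnostics collected in ``df.attrs["diagnostics"]`` (also emitted
    as warnings).  Missing mandatory columns raise :class:`SchemaError`.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")
    for c in QTL_COLUMNS:
        if c not in df.columns:
            df[c] = np.nan

    diagnostics: list[str] = []
    keep = np.ones(len(df), dtype=bool)
    pve = pd.to_numeric(df["effect_size_pve"], errors="coerce")
    lod = pd.to_numeric(df["lod"], errors="coerce")
    nlp = pd.to_numeric(df["neglog10_p"], errors="coerce")
    ss = pd.to_numeric(df["sample_size"], errors="coerce")
    inter = df["cross_type"].astype(str) == "interspecific"
    species_differ = df["species_a"].astype(str) != df["species_b"].astype(str)

    checks = [
        (~((pve > 0) & (pve <= 100)), "effect_size_pve outside (0, 100]"),
        (~(ss > 0), "sample_size must be positive"),
        (lod.isna() & nlp.isna(), "neither lod nor neglog10_p present"),
        ((lod < 0).fillna(False), "negative lod"),
        ((nlp < 0).fillna(False), "negative neglog10_p"),
        (inter != species_differ, "cross_type inconsistent with species pair"),
    ]
    for bad, msg in checks:
        bad = np.asarray(bad, dtype=bool) & keep
        for i in np.flatnonzero(bad):
            diagnostics.append(f"line {i + 2}: {msg}")  # +2: header + 1-based
        keep &= ~bad

    if diagnostics:
        warnings.warn(
            f"rejected {int((~keep).sum())} row(s) from {path}: "
            + "; ".join(diagnostics[:10]),
            stacklevel=2,
        )
    out = df.loc[keep, QTL_COLUMNS].reset_index(drop=True)
    out["effect_size_pve"] = pd.to_numeric(out["effect_size_pve"])
    out["sample_size"] = pd.to_numeric(out["sample_size"])
    for c in ("lod", "neglog10_p", "generations_diverged", "years_diverged"):
        out[c] = pd.to_numeric(out[c], errors="coerce")
    out.attrs["diagnostics"] = diagnostics
    return out


def write_qtl_csv(records: pd.DataFrame, path) -> None:
    cols = [c for c in QTL_COLUMNS if c in records.columns]
    records.to_csv(path, index=False, columns=cols)


# ---------------------------------------------------------------------------
# plink bed/bim/fam
# ---------------------------------------------------------------------------

_BED_MAGIC = b"\x6c\x1b"
# 2-bit codes in SNP-major bed: 00 hom a1 (dosage 2), 01 missing,
# 10 het (dosage 1), 11 hom a2 (dosage 0)
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


def write_bed(panel: GenotypePanel, prefix) -> None:
    """Write a panel as a plink bed/bim/fam triple (SNP-major layout)."""
    prefix = Path(prefix)
    n, m = panel.n_lines, panel.n_snps
    dos = panel.dosages
    codes = np.full((m, n), 1, dtype=np.uint8)  # default: missing (01)
    codes[(dos.T == 2)] = 0
    codes[(dos.T == 1)] = 2
    codes[(dos.T == 0)] = 3
    n_bytes = (n + 3) // 4
    padded = np.zeros((m, n_bytes * 4), dtype=np.uint8)
    padded[:, :n] = codes
    packed = (
        padded[:, 0::4]
        | (padded[:, 1::4] << 2)
        | (padded[:, 2::4] << 4)
        | (padded[:, 3::4] << 6)
    )
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + b"\x01")
        fh.write(packed.tobytes())

    bim = pd.DataFrame(
        {
            "chrom": panel.snps["chrom"],
            "snp": panel.snps.index,
            "cm": 0,
            "pos": panel.snps["pos"],
            "a1": panel.snps["a1"],
            "a2": panel.snps["a2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": panel.line_ids,
            "iid": panel.line_ids,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep=" ", header=False, index=False)


def read_bed(prefix) -> GenotypePanel:
    """Read a plink bed/bim/fam triple into a genotype panel.

    Dosages count the a1 (first/minor) allele.  Only the SNP-major
    layout (third magic byte 0x01) is supported.
    """
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    n, m = len(fam), len(bim)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:2] != _BED_MAGIC:
        raise FormatError("bad bed magic bytes")
    if raw[2:3] != b"\x01":
        raise FormatError("only SNP-major bed files are supported")
    n_bytes = (n + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if body.size != m * n_bytes:
        raise FormatError(
            f"bed payload has {body.size} bytes; expected {m * n_bytes}"
        )
    body = body.reshape(m, n_bytes)
    codes = np.empty((m, n_bytes * 4), dtype=np.uint8)
    codes[:, 0::4] = body & 0b11
    codes[:, 1::4] = (body >> 2) & 0b11
    codes[:, 2::4] = (body >> 4) & 0b11
    codes[:, 3::4] = (body >> 6) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T  # lines x SNPs

    snps = bim.set_index("snp")[["chrom", "pos", "a1", "a2"]]
    snps.index.name = "snp_id"
    finite = dosages[np.isfinite(dosages)]
    inbred = finite.size > 0 and not np.any(finite == 1.0)
    return GenotypePanel(
        line_ids=fam["iid"].tolist(),
        snps=snps,
        dosages=dosages,
        inbred=inbred,
        metadata={"source": str(prefix)},
    )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path) -> GenotypePanel:
    """Read a (plain or bgzipped) VCF into a genotype panel.

    Dosage counts the first ALT allele; ``./.`` becomes missing; any
    non-diploid genotype raises a record-level error.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    line_ids = list(vcf.samples)
    rows, meta = [], []
    for var in vcf:
        gts = var.genotypes  # [allele1, allele2, phased]
        dos = np.empty(len(line_ids))
        for i, g in enumerate(gts):
            alleles = g[:-1]
            if len(alleles) != 2:
                raise FormatError(
                    f"{var.CHROM}:{var.POS}: ploidy {len(alleles)} != 2"
                )
            if alleles[0] < 0 or alleles[1] < 0:
                dos[i] = np.nan
            else:
                dos[i] = float(sum(a == 1 for a in alleles))
        rows.append(dos)
        vid = var.ID or f"{var.CHROM}_{var.POS}"
        alt = var.ALT[0] if var.ALT else "."
        meta.append((vid, var.CHROM, var.POS, alt, var.REF))
    if not rows:
        raise FormatError(f"no variant records in {path}")
    snps = pd.DataFrame(
        meta, columns=["snp_id", "chrom", "pos", "a1", "a2"]
    ).set_index("snp_id")
    dosages = np.asarray(rows).T
    finite = dosages[np.isfinite(dosages)]
    inbred = finite.size > 0 and not np.any(finite == 1.0)
    return GenotypePanel(
        line_ids=line_ids,
        snps=snps,
        dosages=dosages,
        inbred=inbred,
        metadata={"source": str(path)},
    )


def write_vcf(panel: GenotypePanel, path) -> None:
    """Minimal diploid GT-only VCF writer (a1 as ALT, a2 as REF)."""
    gt_map = {2.0: "1/1", 1.0: "0/1", 0.0: "0/0"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.line_ids)
            + "\n"
        )
        for j, (sid, row) in enumerate(panel.snps.iterrows()):
            gts = [
                gt_map.get(panel.dosages[i, j], "./.")
                for i in range(panel.n_lines)
            ]
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{sid}\t{row['a2']}\t"
                f"{row['a1']}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_genotypes(path, fmt: str | None = None) -> GenotypePanel:
    """Dispatch to the bed or VCF reader (inferred from the name if needed)."""
    p = str(path)
    if fmt is None:
        fmt = "vcf" if p.endswith((".vcf", ".vcf.gz")) else "bed"
    if fmt == "vcf":
        return read_vcf(path)
    if fmt == "bed":
        prefix = p[:-4] if p.endswith(".bed") else p
        return read_bed(prefix)
    raise ValueError(f"unknown genotype format {fmt!r}")


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def read_phen(path) -> pd.Series:
    """Read a .phen file: family id, individual id, value per line.

    ``NA`` and ``-9`` map to missing.  Returns a Series indexed by
    individual id; duplicate individuals raise.
    """
    ids, vals = [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: expected >= 3 columns")
            _, iid, raw = parts[0], parts[1], parts[2]
            if raw in ("NA", "-9", "nan"):
                val = np.nan
            else:
                try:
                    val = float(raw)
                except ValueError as exc:
                    raise FormatError(
                        f"{path}:{ln}: non-numeric value {raw!r}"
                    ) from exc
                if val == -9.0:
                    val = np.nan
            ids.append(iid)
            vals.append(val)
    s = pd.Series(vals, index=pd.Index(ids, name="line_id"), name=Path(path).stem)
    if s.index.has_duplicates:
        dups = s.index[s.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate individual ids {dups[:5]!r}")
    return s


def write_phen(values: pd.Series, path, family_ids=None) -> None:
    with open(path, "w") as fh:
        for iid, val in values.items():
            fid = iid if family_ids is None else family_ids[iid]
            out = "-9" if not np.isfinite(val) else repr(float(val))
            fh.write(f"{fid} {iid} {out}\n")


def aggregate_replicates(raw: pd.DataFrame) -> pd.DataFrame:
    """Mean per line and trait over replicate measurements.

    ``raw`` is long-format with columns ``line_id``, ``trait``,
    ``value``; missing replicates are ignored in the mean.  Returns a
    lines x traits table with replicate counts in
    ``attrs["replicate_counts"]`` and the aggregation rule recorded in
    ``attrs["aggregation"]``.
    """
    for c in ("line_id", "trait", "value"):
        if c not in raw.columns:
            raise SchemaError(f"replicate table needs column {c!r}")
    wide = raw.pivot_table(index="line_id", columns="trait", values="value", aggfunc="mean")
    counts = raw.dropna(subset=["value"]).groupby(["line_id", "trait"]).size()
    wide.attrs["replicate_counts"] = counts
    wide.attrs["aggregation"] = "mean"
    return wide
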