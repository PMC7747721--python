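"""Readers, writers and the in-memory data model shared by every stage.

Conventions
-----------
* Beta matrices are :class:`pandas.DataFrame` objects with probes as the
  row index and samples as columns, values in [0, 1], NaN allowed.
* Probe manifests are DataFrames indexed by ``probe_id`` with columns
  ``chrom, pos, gene, feature, cgi_relation, on_450k, on_epic``.
  Coordinates are 1-based (Illumina MAPINFO convention); region spans are
  ``max(pos) - min(pos)``.
* Sample sheets are DataFrames indexed by ``sample_id`` with at least
  ``group`` (case/control) and ``cohort``; ``batch`` holds the slide.
* Genotypes live in :class:`GenotypeData`: minor-allele dosage coding
  0/1/2 with -1 for missing, plus a per-SNP map table.

On disk: beta/detection-P/beadcount matrices are TSV (first column
``probe_id``), manifest and sample sheet are CSV, genotypes are PLINK
text PED/MAP.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

FEATURES = ("TSS1500", "TSS200", "5'UTR", "1stExon", "Body", "3'UTR", "intergenic")
CGI_RELATIONS = ("Island", "Shore", "Shelf", "OpenSea")

MANIFEST_COLUMNS = ["chrom", "pos", "gene", "feature", "cgi_relation", "on_450k", "on_epic"]

MISSING = -1  # genotype missing code


class DataIOError(ValueError):
    """Raised for malformed or inconsistent on-disk inputs."""


# ---------------------------------------------------------------------------
# genotype container
# ---------------------------------------------------------------------------


@dataclass
class GenotypeData:
    """Unphased biallelic genotypes with PLINK-style map information.

    Attributes
    ----------
    sample_ids : list of str
    snps : DataFrame indexed by snp_id with columns chrom, pos, allele1, allele2.
        ``allele1`` is the minor allele as determined from the data;
        positions are 1-based and strictly increasing within a chromosome.
    genotypes : int8 array, shape (n_samples, n_snps)
        Count of minor-allele copies (0 hom-major, 1 het, 2 hom-minor),
        ``MISSING`` (-1) for no-calls.
    phenotypes : optional per-sample PED phenotype column (kept verbatim).
    """

    sample_ids: list[str]
    snps: pd.DataFrame
    genotypes: np.ndarray
    phenotypes: pd.Series | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.sample_ids), len(self.snps)):
            raise DataIOError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snps)} SNPs"
            )
        if not self.snps.index.is_unique:
            raise DataIOError("duplicate SNP ids")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise DataIOError("genotype codes must be 0/1/2 or -1 (missing)")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def snp_index(self, snp_id: str) -> int:
        try:
            return int(self.snps.index.get_loc(snp_id))
        except KeyError:
            raise KeyError(f"unknown SNP {snp_id!r}") from None

    def column(self, snp_id: str) -> np.ndarray:
        """Minor-allele dosages for one SNP, missing as -1."""
        return self.genotypes[:, self.snp_index(snp_id)]

    def subset_snps(self, keep: np.ndarray) -> "GenotypeData":
        keep = np.asarray(keep)
        return GenotypeData(
            sample_ids=list(self.sample_ids),
            snps=self.snps.iloc[keep] if keep.dtype.kind in "iu" else self.snps.loc[keep],
            genotypes=self.genotypes[:, keep],
            phenotypes=self.phenotypes,
        )

    def subset_samples(self, keep_mask: np.ndarray) -> "GenotypeData":
        keep_mask = np.asarray(keep_mask, dtype=bool)
        return GenotypeData(
            sample_ids=[s for s, k in zip(self.sample_ids, keep_mask) if k],
            snps=self.snps,
            genotypes=self.genotypes[keep_mask],
            phenotypes=None if self.phenotypes is None else self.phenotypes[keep_mask],
        )

    def allele_counts(self) -> pd.DataFrame:
        """Per-SNP counts of minor and major allele copies (missing excluded)."""
        g = self.genotypes
        obs = g != MISSING
        minor = np.where(obs, g, 0).sum(axis=0)
        total = 2 * obs.sum(axis=0)
        return pd.DataFrame(
            {"minor": minor, "major": total - minor}, index=self.snps.index
        )


# ---------------------------------------------------------------------------
# validation helpers
# ---------------------------------------------------------------------------


def validate_beta(beta: pd.DataFrame, *, name: str = "beta") -> pd.DataFrame:
    if not beta.index.is_unique:
        raise DataIOError(f"{name}: duplicate probe ids")
    if not beta.columns.is_unique:
        raise DataIOError(f"{name}: duplicate sample ids")
    values = beta.to_numpy(dtype=float)
    bad = (values < 0) | (values > 1)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise DataIOError(
            f"{name}: value {values[i, j]!r} outside [0, 1] at probe "
            f"{beta.index[i]!r}, sample {beta.columns[j]!r}"
        )
    return beta


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise DataIOError(f"manifest missing columns: {missing}")
    if not manifest.index.is_unique:
        raise DataIOError("manifest: duplicate probe ids")
    if (manifest["pos"] < 1).any():
        raise DataIOError("manifest: positions must be >= 1 (1-based)")
    bad_cgi = set(manifest["cgi_relation"]) - set(CGI_RELATIONS)
    if bad_cgi:
        raise DataIOError(f"manifest: unknown cgi_relation values {sorted(bad_cgi)}")
    return manifest


def validate_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    if not sheet.index.is_unique:
        raise DataIOError("sample sheet: duplicate sample ids")
    for col in ("group", "cohort"):
        if col not in sheet.columns:
            raise DataIOError(f"sample sheet missing column {col!r}")
        if sheet[col].isna().any():
            raise DataIOError(f"sample sheet: missing values in {col!r}")
    bad = set(sheet["group"]) - {"case", "control"}
    if bad:
        raise DataIOError(f"sample sheet: group must be case/control, got {sorted(bad)}")
    return sheet


def primary_gene(gene: str) -> str:
    """Grouping key for possibly ';'-separated multi-gene annotations.

    The first listed gene is the key; the empty string marks an
    unannotated (intergenic) probe.
    """
    if not gene or (isinstance(gene, float) and np.isnan(gene)):
        return ""
    return str(gene).split(";")[0].strip()


# ---------------------------------------------------------------------------
# beta bundle
# ---------------------------------------------------------------------------


def _read_matrix(path: str) -> pd.DataFrame:
    # round_trip parsing: write->read must reproduce floats bit-exactly
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str},
                     float_precision="round_trip")
    df = df.set_index(df.columns[0])
    df.index.name = "probe_id"
    return df


def read_beta_bundle(path_prefix: str):
    """Read a ``<prefix>_beta.tsv`` bundle and cross-validate its labels.

    Expects ``<prefix>_beta.tsv``, ``<prefix>_manifest.csv`` and
    ``<prefix>_samples.csv``; ``<prefix>_detp.tsv`` and
    ``<prefix>_beadcount.tsv`` are optional companions sharing beta's
    layout.

    Returns ``(beta, detp, beadcount, manifest, sheet)`` with ``detp`` /
    ``beadcount`` as None when absent.
    """
    beta = validate_beta(_read_matrix(path_prefix + "_beta.tsv"))
    manifest = read_manifest(path_prefix + "_manifest.csv")
    sheet = read_sample_sheet(path_prefix + "_samples.csv")

    unknown_probes = beta.index.difference(manifest.index)
    if len(unknown_probes):
        raise DataIOError(f"beta probes absent from manifest: {list(unknown_probes[:5])}")
    unknown_samples = beta.columns.difference(sheet.index)
    if len(unknown_samples):
        raise DataIOError(f"beta samples absent from sample sheet: {list(unknown_samples[:5])}")

    detp = beadcount = None
    if os.path.exists(path_prefix + "_detp.tsv"):
        detp = _read_matrix(path_prefix + "_detp.tsv")
        _check_companion(beta, detp, "detection-P")
    if os.path.exists(path_prefix + "_beadcount.tsv"):
        beadcount = _read_matrix(path_prefix + "_beadcount.tsv")
        _check_companion(beta, beadcount, "beadcount")
    return beta, detp, beadcount, manifest, sheet


def _check_companion(beta: pd.DataFrame, companion: pd.DataFrame, name: str) -> None:
    if companion.shape != beta.shape or not (
        companion.index.equals(beta.index) and companion.columns.equals(beta.columns)
    ):
        raise DataIOError(f"{name} matrix does not share beta's probe/sample layout")


def write_beta_bundle(
    path_prefix: str,
    beta: pd.DataFrame,
    manifest: pd.DataFrame,
    sheet: pd.DataFrame,
    detp: pd.DataFrame | None = None,
    beadcount: pd.DataFrame | None = None,
) -> None:
    beta.to_csv(path_prefix + "_beta.tsv", sep="\t", index_label="probe_id")
    manifest.to_csv(path_prefix + "_manifest.csv", index_label="probe_id")
    sheet.to_csv(path_prefix + "_samples.csv", index_label="sample_id")
    if detp is not None:
        detp.to_csv(path_prefix + "_detp.tsv", sep="\t", index_label="probe_id")
    if beadcount is not None:
        beadcount.to_csv(path_prefix + "_beadcount.tsv", sep="\t", index_label="probe_id")


def read_manifest(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", dtype={"probe_id": str, "chrom": str, "gene": str})
    df = df.set_index("probe_id")
    df["gene"] = df["gene"].fillna("")
    df["pos"] = df["pos"].astype(np.int64)
    for col in ("on_450k", "on_epic"):
        df[col] = df[col].astype(bool)
    return validate_manifest(df)


def read_sample_sheet(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", dtype={"sample_id": str, "batch": str})
    df = df.set_index("sample_id")
    return validate_sheet(df)


# ---------------------------------------------------------------------------
# PLINK text PED/MAP
# ---------------------------------------------------------------------------


def read_ped_map(ped_path: str, map_path: str) -> GenotypeData:
    """Parse PLINK's text PED/MAP dialect into :class:`GenotypeData`.

    Allele pairs are collapsed to minor-allele dosage against the
    per-SNP minor/major alleles determined from the data; ``0 0`` pairs
    become missing. A SNP with more than two observed alleles is an
    error (biallelic only).
    """
    snps = pd.read_csv(
        map_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos"],
        dtype={"chrom": str, "snp_id": str},
    )
    if not snps["snp_id"].is_unique:
        raise DataIOError("MAP: duplicate SNP ids")
    n_snps = len(snps)

    sample_ids: list[str] = []
    phenos: list[str] = []
    raw_pairs: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_snps:
                raise DataIOError(
                    f"PED line {ln}: expected {6 + 2 * n_snps} columns "
                    f"(6 + 2x{n_snps} alleles), got {len(fields)}"
                )
            sample_ids.append(fields[1])
            phenos.append(fields[5])
            alleles = fields[6:]
            raw_pairs.append(
                [(alleles[2 * j], alleles[2 * j + 1]) for j in range(n_snps)]
            )

    n_samples = len(sample_ids)
    genotypes = np.full((n_samples, n_snps), MISSING, dtype=np.int8)
    allele1 = []
    allele2 = []
    for j in range(n_snps):
        counts: dict[str, int] = {}
        for i in range(n_samples):
            for a in raw_pairs[i][j]:
                if a != "0":
                    counts[a] = counts.get(a, 0) + 1
        if len(counts) > 2:
            raise DataIOError(
                f"SNP {snps['snp_id'][j]!r}: more than two alleles observed "
                f"({sorted(counts)})"
            )
        # minor first; deterministic tie-break on allele name
        ordered = sorted(counts.items(), key=lambda kv: (kv[1], kv[0]))
        if len(ordered) == 0:
            minor, major = "0", "0"
        elif len(ordered) == 1:
            minor, major = "0", ordered[0][0]  # monomorphic: no minor allele seen
        else:
            minor, major = ordered[0][0], ordered[1][0]
        allele1.append(minor)
        allele2.append(major)
        for i in range(n_samples):
            a, b = raw_pairs[i][j]
            if a == "0" or b == "0":
                if a != b:
                    raise DataIOError(
                        f"PED sample {sample_ids[i]!r} SNP {snps['snp_id'][j]!r}: "
                        f"half-missing allele pair ({a}, {b})"
                    )
                continue
            genotypes[i, j] = (a == minor) + (b == minor)

    snps = snps.assign(allele1=allele1, allele2=allele2).set_index("snp_id")
    snps = snps.drop(columns=["cm"])
    return GenotypeData(
        sample_ids=sample_ids,
        snps=snps,
        genotypes=genotypes,
        phenotypes=pd.Series(phenos, index=sample_ids, name="phenotype"),
    )


def write_ped_map(g: GenotypeData, ped_path: str, map_path: str) -> None:
    """Write PLINK text PED/MAP (inverse of :func:`read_ped_map`)."""
    with open(map_path, "w") as fh:
        for snp_id, row in g.snps.iterrows():
            fh.write(f"{row['chrom']}\t{snp_id}\t0\t{row['pos']}\n")
    pheno = g.phenotypes
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(g.sample_ids):
            ph = "0" if pheno is None else str(pheno.iloc[i])
            fields = [sid, sid, "0", "0", "0", ph]
            for j, (_, row) in enumerate(g.snps.iterrows()):
                code = g.genotypes[i, j]
                minor, major = row["allele1"], row["allele2"]
                if code == MISSING:
                    fields += ["0", "0"]
                elif code == 0:
                    fields += [major, major]
                elif code == 1:
                    fields += [minor, major]
                else:
                    fields += [minor, minor]
            fh.write(" ".join(fields) + "\n")
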