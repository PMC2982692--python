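"""Genotype matrix I/O: PLINK ped/map text files and a simple TSV dialect.

Genotype calls are stored as small integer codes over the fixed category
order ``AA < Aa < aa < missing`` (major homozygote, heterozygote, minor
homozygote, missing).  Major/minor orientation is computed from the observed
data: the most frequent non-missing allele at a SNP is the major allele,
with ties broken toward the lexicographically smaller allele.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

#: canonical genotype categories, in tie-break order
CATEGORIES = ("AA", "Aa", "aa", "missing")
CODE = {c: i for i, c in enumerate(CATEGORIES)}
AA, AB, BB, MISSING = 0, 1, 2, 3

#: phenotype column convention in ped files
_PED_PHENOTYPES = {"1": "control", "2": "case", "0": None, "-9": None}


class GenotypeFormatError(ValueError):
    """Raised for malformed ped/map or TSV genotype input."""


@dataclasses.dataclass(frozen=True)
class SNPMeta:
    """Identity and location of one SNP.

    ``alleles`` is the (major, minor) nucleotide pair when known.
    ``position`` is 1-based, in base pairs.
    """

    snp_id: str
    chromosome: str = "0"
    position: int = 0
    alleles: tuple[str, str] | None = None


@dataclasses.dataclass
class GenotypeMatrix:
    """n samples x p SNPs of categorical genotype calls plus class labels.

    ``calls`` is an (n, p) int8 array of codes into :data:`CATEGORIES`.
    ``labels`` is a length-n object array of class labels, or None when the
    input carried no phenotype.
    """

    samples: list[str]
    labels: np.ndarray | None
    snps: list[SNPMeta]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if len(self.labels) != len(self.samples):
                raise ValueError("labels and samples length mismatch")
        if self.calls.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.samples)}, {len(self.snps)})"
            )
        if self.calls.size and (self.calls.min() < 0 or self.calls.max() > 3):
            raise ValueError("calls contain codes outside the 4 categories")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate snp_id in dataset")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def classes(self) -> list:
        """Distinct class labels, in sorted order."""
        if self.labels is None:
            raise ValueError("matrix has no labels")
        if any(l is None for l in self.labels):
            raise ValueError("matrix contains unlabeled samples")
        return sorted(set(self.labels))

    def missing_fraction(self) -> np.ndarray:
        """Per-SNP fraction of missing calls over all samples."""
        return (self.calls == MISSING).mean(axis=0)

    def subset_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            labels=None if self.labels is None else self.labels[idx],
            snps=self.snps,
            calls=self.calls[idx],
        )

    def subset_snps(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            samples=self.samples,
            labels=self.labels,
            snps=[self.snps[i] for i in idx],
            calls=self.calls[:, idx],
        )


def _canonical_token(tok: str, missing_token: str) -> int:
    if tok == missing_token:
        return MISSING
    if tok in ("Aa", "aA"):
        return AB
    if tok in CODE:
        return CODE[tok]
    raise GenotypeFormatError(f"unknown genotype token {tok!r}")


def read_genotype_tsv(path, missing_token: str = "NN") -> GenotypeMatrix:
    """Read the TSV dialect: header ``sample_id<TAB>label<TAB><snp ids...>``,
    one row per sample with genotype strings from {AA, Aa, aa, NN}.

    The heterozygote is symmetric, so ``aA`` is canonicalized to ``Aa``.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 3:
            raise GenotypeFormatError(f"{path}: header needs sample_id, label, >=1 SNP")
        snp_ids = header[2:]
        samples, labels, rows = [], [], []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise GenotypeFormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            samples.append(fields[0])
            labels.append(fields[1] if fields[1] not in ("", "NA") else None)
            row = []
            for j, tok in enumerate(fields[2:]):
                try:
                    row.append(_canonical_token(tok, missing_token))
                except GenotypeFormatError as e:
                    raise GenotypeFormatError(
                        f"{path}:{lineno}: column {snp_ids[j]}: {e}"
                    ) from None
            rows.append(row)
    label_arr = None if all(l is None for l in labels) else np.array(labels, dtype=object)
    return GenotypeMatrix(
        samples=samples,
        labels=label_arr,
        snps=[SNPMeta(snp_id=s) for s in snp_ids],
        calls=np.array(rows, dtype=np.int8).reshape(len(samples), len(snp_ids)),
    )


def write_genotype_tsv(g: GenotypeMatrix, path, missing_token: str = "NN") -> None:
    """Write the TSV dialect; inverse of :func:`read_genotype_tsv`."""
    strings = list(CATEGORIES[:3]) + [missing_token]
    with open(path, "w") as fh:
        fh.write("sample_id\tlabel\t" + "\t".join(g.snp_ids) + "\n")
        for i, sid in enumerate(g.samples):
            lab = "" if g.labels is None or g.labels[i] is None else str(g.labels[i])
            row = "\t".join(strings[c] for c in g.calls[i])
            fh.write(f"{sid}\t{lab}\t{row}\n")


def _read_map(map_path) -> list[SNPMeta]:
    snps = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 4:
                raise GenotypeFormatError(
                    f"{map_path}:{lineno}: map rows need chrom, id, cM, position"
                )
            snps.append(
                SNPMeta(snp_id=fields[1], chromosome=fields[0], position=int(fields[3]))
            )
    return snps


def read_ped_map(ped_path, map_path) -> GenotypeMatrix:
    """Read PLINK text ped/map into categorical AA/Aa/aa calls.

    Allele pairs are collapsed relative to the major allele observed in the
    data; ``0 0`` is the missing genotype.  The ped phenotype column is
    mapped 1 -> "control", 2 -> "case" (0 / -9 -> unlabeled); any other
    value is kept verbatim as a class label.
    """
    snps = _read_map(map_path)
    p = len(snps)
    samples, labels, allele_rows = [], [], []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 6 + 2 * p:
                raise GenotypeFormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * p} fields "
                    f"(6 + 2x{p} alleles), got {len(fields)}"
                )
            samples.append(fields[1])
            labels.append(_PED_PHENOTYPES.get(fields[5], fields[5]))
            allele_rows.append(fields[6:])
    n = len(samples)
    calls = np.full((n, p), MISSING, dtype=np.int8)
    resolved = []
    for j, meta in enumerate(snps):
        a1 = [row[2 * j] for row in allele_rows]
        a2 = [row[2 * j + 1] for row in allele_rows]
        counts: dict[str, int] = {}
        for a in a1 + a2:
            if a != "0":
                counts[a] = counts.get(a, 0) + 1
        if len(counts) > 2:
            raise GenotypeFormatError(
                f"{ped_path}: SNP {meta.snp_id}: >2 distinct alleles {sorted(counts)}"
            )
        # major = most frequent; ties -> lexicographically smaller allele
        ordered = sorted(counts, key=lambda a: (-counts[a], a))
        major = ordered[0] if ordered else None
        minor = ordered[1] if len(ordered) > 1 else None
        for i in range(n):
            x, y = a1[i], a2[i]
            if x == "0" or y == "0":
                if x != y:
                    raise GenotypeFormatError(
                        f"{ped_path}: SNP {meta.snp_id}, sample {samples[i]}: "
                        f"half-missing genotype {x}/{y}"
                    )
                continue
            if x == y:
                calls[i, j] = AA if x == major else BB
            else:
                calls[i, j] = AB
        resolved.append(
            dataclasses.replace(
                meta, alleles=(major, minor) if major is not None else None
            )
        )
    label_arr = None if all(l is None for l in labels) else np.array(labels, dtype=object)
    return GenotypeMatrix(samples=samples, labels=label_arr, snps=resolved, calls=calls)


def write_ped_map(g: GenotypeMatrix, ped_path, map_path,
                  label_codes: dict | None = None) -> None:
    """Write PLINK text ped/map.  SNPs lacking allele metadata use A/G.

    ``label_codes`` maps class labels to phenotype integers; by default
    "control" -> 1 and "case" -> 2, other labels numbered in sorted order.
    """
    with open(map_path, "w") as fh:
        for s in g.snps:
            fh.write(f"{s.chromosome}\t{s.snp_id}\t0\t{s.position}\n")
    if label_codes is None:
        label_codes = {}
        if g.labels is not None:
            uniq = sorted(set(g.labels))
            if set(uniq) <= {"control", "case"}:
                label_codes = {"control": 1, "case": 2}
            else:
                label_codes = {lab: i + 1 for i, lab in enumerate(uniq)}
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(g.samples):
            pheno = "0"
            if g.labels is not None and g.labels[i] is not None:
                pheno = str(label_codes[g.labels[i]])
            parts = [f"F{i + 1}", sid, "0", "0", "0", pheno]
            for j, meta in enumerate(g.snps):
                major, minor = meta.alleles if meta.alleles else ("A", "G")
                if minor is None:
                    minor = "G" if major != "G" else "A"
                c = g.calls[i, j]
                pair = {AA: (major, major), AB: (major, minor),
                        BB: (minor, minor), MISSING: ("0", "0")}[c]
                parts.extend(pair)
            fh.write(" ".join(parts) + "\n")


def filter_by_missingness(
    g: GenotypeMatrix, max_missing_fraction: float
) -> tuple[GenotypeMatrix, list[str]]:
    """Keep SNPs whose missing fraction over all samples is <= the threshold.

    Returns the filtered matrix (SNP order preserved) and the list of
    dropped SNP ids.  A threshold of 0.01 implements the rule that SNPs
    with more than 1% missing genotypes are not considered.
    """
    if not 0 <= max_missing_fraction <= 1:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    frac = g.missing_fraction()
    keep = frac <= max_missing_fraction
    dropped = [s.snp_id for s, k in zip(g.snps, keep) if not k]
    return g.subset_snps(np.flatnonzero(keep)), dropped
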