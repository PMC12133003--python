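"""Genotype data model and I/O for multi-sample VCF and sample→cultivar tables.

Genotypes are stored as small-integer codes per (sample, locus) call:

======  ==========================
code    meaning
======  ==========================
``0``   homozygous reference
``1``   heterozygous
``2``   homozygous alternate
``-1``  missing (``MISSING``)
======  ==========================

Coding is phase- and order-agnostic (``0/1``, ``1/0`` and ``1|0`` are all
code 1).  A half-missing call (``./1``) is treated as missing: a single
observed allele does not determine a diploid genotype.  Calls that involve
an allele index above 1 (multi-allelic records) are coded missing; the
records themselves are retained and flagged so the biallelic filter in
:mod:`corepanel.core_selection` is the single place that removes and counts
them.

Coordinates follow the VCF convention: 1-based, inclusive positions.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from cyvcf2 import VCF

__all__ = [
    "MISSING",
    "Locus",
    "GenotypeMatrix",
    "VarietyAssignment",
    "VcfFormatError",
    "ValidationError",
    "read_vcf",
    "write_vcf",
    "read_variety_map",
    "write_variety_map",
]

#: Sentinel genotype code for a missing call.  Never conflated with code 0.
MISSING: int = -1

_BASES = frozenset("ACGT")


class VcfFormatError(ValueError):
    """Raised when a VCF cannot be parsed or lacks required FORMAT fields."""


class ValidationError(ValueError):
    """Raised when inputs violate the data-model invariants."""


@dataclasses.dataclass(frozen=True)
class Locus:
    """A variant site.

    Parameters
    ----------
    chrom : str
        Chromosome identifier.
    pos : int
        1-based position.
    ref : str
        Reference allele.
    alt : tuple of str
        Alternate allele(s); more than one marks the record multi-allelic.
    id : str
        Locus label; synthesized as ``chrom:pos`` when the VCF has none.
    """

    chrom: str
    pos: int
    ref: str
    alt: tuple[str, ...]
    id: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"locus position must be >= 1, got {self.pos}")
        if not self.alt:
            raise ValidationError("locus must carry at least one alt allele")
        if self.ref in self.alt:
            raise ValidationError(f"ref allele {self.ref!r} repeated in alt {self.alt}")
        if not self.id:
            object.__setattr__(self, "id", f"{self.chrom}:{self.pos}")

    @property
    def is_biallelic_snp(self) -> bool:
        """True for a single-base ref and exactly one single-base ACGT alt.

        Any non-ACGT allele (spanning deletions ``*``, symbolic alleles,
        indels) disqualifies the locus, as does more than one alt.
        """
        return (
            len(self.alt) == 1
            and self.ref in _BASES
            and self.alt[0] in _BASES
        )


@dataclasses.dataclass
class GenotypeMatrix:
    """Samples × loci diploid genotype codes with per-call depth.

    ``genotypes`` and ``depths`` are ``n_samples × n_loci`` arrays; codes are
    in ``{0, 1, 2, MISSING}``, depths are non-negative integers (0 when the
    VCF carried no DP).  Loci are kept sorted by (chrom, pos).
    """

    samples: list[str]
    loci: list[Locus]
    genotypes: np.ndarray
    depths: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.depths = np.asarray(self.depths, dtype=np.int32)
        shape = (len(self.samples), len(self.loci))
        if self.genotypes.shape != shape or self.depths.shape != shape:
            raise ValidationError(
                f"matrix shapes {self.genotypes.shape}/{self.depths.shape} "
                f"do not match samples x loci {shape}"
            )
        if len(set(self.samples)) != len(self.samples):
            dupes = [s for s, c in Counter(self.samples).items() if c > 1]
            raise ValidationError(f"duplicate sample names: {dupes}")
        valid = (self.genotypes >= 0) & (self.genotypes <= 2)
        if not bool(np.all(valid | (self.genotypes == MISSING))):
            raise ValidationError("genotype codes must be in {0, 1, 2, MISSING}")
        if np.any(self.depths < 0):
            raise ValidationError("depths must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def locus_ids(self) -> list[str]:
        return [loc.id for loc in self.loci]

    def subset_loci(self, indices: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the loci at ``indices`` (order preserved)."""
        idx = np.asarray(indices, dtype=np.intp)
        return GenotypeMatrix(
            samples=list(self.samples),
            loci=[self.loci[i] for i in idx],
            genotypes=self.genotypes[:, idx].copy(),
            depths=self.depths[:, idx].copy(),
        )

    def subset_samples(self, indices: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(indices, dtype=np.intp)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            loci=list(self.loci),
            genotypes=self.genotypes[idx, :].copy(),
            depths=self.depths[idx, :].copy(),
        )


@dataclasses.dataclass
class VarietyAssignment:
    """Mapping from sample label to cultivar label."""

    mapping: dict[str, str]

    @property
    def varieties(self) -> list[str]:
        """Cultivar labels in first-appearance order."""
        seen: dict[str, None] = {}
        for v in self.mapping.values():
            seen.setdefault(v, None)
        return list(seen)

    def groups(self) -> dict[str, list[str]]:
        """Cultivar → member samples, preserving input order."""
        out: dict[str, list[str]] = {v: [] for v in self.varieties}
        for s, v in self.mapping.items():
            out[v].append(s)
        return out

    def require_complete(self, samples: Iterable[str]) -> None:
        """Raise unless every sample is assigned to a cultivar."""
        missing = [s for s in samples if s not in self.mapping]
        if missing:
            raise ValidationError(f"samples without cultivar assignment: {missing}")

    def group_indices(self, samples: Sequence[str]) -> dict[str, np.ndarray]:
        """Cultivar → integer row indices into the given sample order."""
        self.require_complete(samples)
        pos = {s: i for i, s in enumerate(samples)}
        return {
            v: np.array([pos[s] for s in members if s in pos], dtype=np.intp)
            for v, members in self.groups().items()
        }


def _code_from_alleles(a0: int, a1: int) -> int:
    if a0 < 0 or a1 < 0:
        return MISSING  # half-missing calls are missing too
    if a0 > 1 or a1 > 1:
        return MISSING  # >1st alt only occurs on multi-allelic records (flagged)
    return a0 + a1


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix`.

    GT is required in FORMAT; DP is used when present (0 otherwise).
    Multi-allelic records are ingested (calls coded missing) and flagged via
    ``Locus.alt`` so downstream filtering can count them.

    Raises
    ------
    VcfFormatError
        If the file cannot be parsed or GT is absent from FORMAT.
    ValidationError
        If sample names are duplicated.
    """
    path = Path(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare Exceptions on bad headers
        raise VcfFormatError(f"cannot parse VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise ValidationError(f"duplicate sample names in VCF {path}")
    n = len(samples)

    loci: list[Locus] = []
    geno_cols: list[np.ndarray] = []
    depth_cols: list[np.ndarray] = []
    for var in vcf:
        if "GT" not in var.FORMAT:
            raise VcfFormatError(
                f"record {var.CHROM}:{var.POS} carries no GT in FORMAT"
            )
        alt = tuple(var.ALT) if var.ALT else ()
        if not alt:
            continue  # no alternate allele: not a variant site
        loci.append(
            Locus(
                chrom=var.CHROM,
                pos=var.POS,
                ref=var.REF,
                alt=alt,
                id=var.ID or "",
            )
        )
        col = np.full(n, MISSING, dtype=np.int8)
        for i, g in enumerate(var.genotypes):
            # cyvcf2 genotype entry: [allele0, allele1, ..., phased]
            if len(g) >= 3:
                col[i] = _code_from_alleles(g[0], g[1])
            elif len(g) == 2:  # haploid call: treat as missing diploid genotype
                col[i] = MISSING
        geno_cols.append(col)

        dp = np.zeros(n, dtype=np.int32)
        if var.FORMAT and "DP" in var.FORMAT:
            raw = var.format("DP")
            if raw is not None:
                raw = np.asarray(raw).reshape(n, -1)[:, 0]
                ok = (raw >= 0) & (raw < np.iinfo(np.int32).max)
                dp[ok] = raw[ok].astype(np.int32)
        depth_cols.append(dp)

    if loci:
        genotypes = np.stack(geno_cols, axis=1)
        depths = np.stack(depth_cols, axis=1)
    else:
        genotypes = np.zeros((n, 0), dtype=np.int8)
        depths = np.zeros((n, 0), dtype=np.int32)

    gm = GenotypeMatrix(samples=samples, loci=loci, genotypes=genotypes, depths=depths)
    return sort_loci(gm)


def sort_loci(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Return ``gm`` with loci sorted by (chrom, pos); stable for ties."""
    order = sorted(range(gm.n_loci), key=lambda i: (gm.loci[i].chrom, gm.loci[i].pos))
    if order == list(range(gm.n_loci)):
        return gm
    return gm.subset_loci(order)


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> Path:
    """Write a :class:`GenotypeMatrix` as VCF 4.2 with GT:DP per call.

    Round-trip contract: ``read_vcf(write_vcf(gm))`` reproduces codes,
    depths, loci and sample order exactly.
    """
    path = Path(path)
    chroms: dict[str, int] = {}
    for loc in gm.loci:
        chroms[loc.chrom] = max(chroms.get(loc.chrom, 0), loc.pos)
    lines = ["##fileformat=VCFv4.2", "##source=corepanel"]
    for chrom, maxpos in chroms.items():
        lines.append(f"##contig=<ID={chrom},length={maxpos + 1}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(gm.samples)
    )
    for j, loc in enumerate(gm.loci):
        fields = [
            loc.chrom,
            str(loc.pos),
            loc.id or ".",
            loc.ref,
            ",".join(loc.alt),
            ".",
            "PASS",
            ".",
            "GT:DP",
        ]
        for i in range(gm.n_samples):
            code = int(gm.genotypes[i, j])
            fields.append(f"{_GT_STRINGS[code]}:{int(gm.depths[i, j])}")
        lines.append("\t".join(fields))
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write VCF to {path}: {exc}") from exc
    return path


_HEADER_TOKENS = {"sample", "sample_id", "id", "name"}


def read_variety_map(path: str | Path) -> VarietyAssignment:
    """Read a two-column (sample, cultivar) TSV; header row optional.

    A first row whose first field is ``sample``/``sample_id``/``id``/``name``
    (case-insensitive) is treated as a header.  A sample listed twice with
    conflicting cultivars is an error; exact duplicate rows are tolerated.
    """
    path = Path(path)
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                parts = line.split()
            if len(parts) < 2:
                raise ValidationError(
                    f"{path}:{lineno}: expected two columns, got {line!r}"
                )
            sample, variety = parts[0].strip(), parts[1].strip()
            if lineno == 1 and sample.lower() in _HEADER_TOKENS:
                continue
            if sample in mapping and mapping[sample] != variety:
                raise ValidationError(
                    f"{path}:{lineno}: sample {sample!r} assigned to both "
                    f"{mapping[sample]!r} and {variety!r}"
                )
            mapping[sample] = variety
    if not mapping:
        raise ValidationError(f"{path}: no sample assignments found")
    return VarietyAssignment(mapping=mapping)


def write_variety_map(assignment: VarietyAssignment | Mapping[str, str],
                      path: str | Path) -> Path:
    """Write a sample→cultivar TSV with a header row."""
    mapping = assignment.mapping if isinstance(assignment, VarietyAssignment) else assignment
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("sample\tvariety\n")
        for sample, variety in mapping.items():
            fh.write(f"{sample}\t{variety}\n")
    return path
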