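"""Core data containers and readers for summary statistics, LD, and allele references.

Summary statistics are held as pandas DataFrames with canonical columns
``id, chrom, pos, a1, a2, beta, se, pvalue, maf`` where ``a1`` is the effect
allele and ``beta`` is the estimated coefficient per copy of ``a1``. Signed
LD (Pearson r between effect-allele dosages) is held as a labelled square
matrix. Two studies (A = exposure/eQTL, B = outcome/GWAS) are joined on SNP
identity with allele-orientation reconciliation so that downstream modelling
sees a single, consistent effect-allele coding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

CANONICAL_COLUMNS = ["id", "chrom", "pos", "a1", "a2", "beta", "se", "pvalue", "maf"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class LocusError(ValueError):
    """Fatal locus-level problem (e.g. no SNPs shared between studies)."""


class FormatError(ValueError):
    """Malformed input file."""


def _complement(allele: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in allele.upper())


def is_palindromic(a1: str, a2: str) -> bool:
    """True for strand-ambiguous pairs (A/T or C/G) whose orientation cannot
    be resolved from the stated alleles alone."""
    return _complement(a1) == a2.upper()


@dataclass(frozen=True)
class SnpRecord:
    """One SNP's association record within a study."""

    id: str
    chrom: str
    pos: int
    a1: str  # effect allele
    a2: str  # other allele
    beta: float
    se: float
    pvalue: float
    maf: float

    def validate(self) -> None:
        if not np.isfinite([self.beta, self.se, self.pvalue, self.maf]).all():
            raise ValueError(f"{self.id}: non-finite field")
        if self.se <= 0:
            raise ValueError(f"{self.id}: se must be > 0 (got {self.se})")
        if not (0 < self.pvalue <= 1):
            raise ValueError(f"{self.id}: pvalue must be in (0, 1] (got {self.pvalue})")
        if not (0 < self.maf <= 0.5):
            raise ValueError(f"{self.id}: maf must be in (0, 0.5] (got {self.maf})")
        if self.a1.upper() == self.a2.upper():
            raise ValueError(f"{self.id}: effect and other allele identical")


@dataclass
class SumStats:
    """Per-study table of SNP association records.

    ``study_label`` is "A" for the exposure (eQTL) study and "B" for the
    outcome (GWAS) study.
    """

    study_label: str
    table: pd.DataFrame
    validation_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.table.columns]
        if missing:
            raise FormatError(f"summary statistics missing columns: {missing}")
        if self.table["id"].duplicated().any():
            dups = self.table.loc[self.table["id"].duplicated(), "id"].tolist()
            raise FormatError(f"duplicate SNP ids: {dups[:5]}")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> list[str]:
        return self.table["id"].tolist()

    def records(self):
        for row in self.table.itertuples(index=False):
            yield SnpRecord(row.id, str(row.chrom), int(row.pos), row.a1, row.a2,
                            float(row.beta), float(row.se), float(row.pvalue),
                            float(row.maf))


@dataclass
class LDMatrix:
    """Signed symmetric Pearson-correlation matrix over SNP effect-allele dosages."""

    ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.ids)
        if self.r.shape != (n, n):
            raise FormatError(f"LD shape {self.r.shape} does not match {n} ids")
        if len(set(self.ids)) != n:
            raise FormatError("duplicate ids in LD matrix")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise FormatError("LD matrix asymmetric beyond 1e-8")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-6):
            raise FormatError("LD matrix diagonal is not 1")
        if np.nanmax(np.abs(self.r)) > 1 + 1e-6:
            raise FormatError("LD entries outside [-1, 1]")
        # exact symmetry and unit diagonal for downstream linear algebra
        self.r = (self.r + self.r.T) / 2.0
        if n:
            np.fill_diagonal(self.r, 1.0)

    def index_of(self, snp_id: str) -> int:
        return self.ids.index(snp_id)

    def subset(self, ids: Sequence[str]) -> "LDMatrix":
        pos = {s: i for i, s in enumerate(self.ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise LocusError(f"SNPs absent from LD matrix: {missing[:5]}")
        idx = np.array([pos[s] for s in ids], dtype=int)
        return LDMatrix(list(ids), self.r[np.ix_(idx, idx)])

    def r2(self, id1: str, id2: str) -> float:
        return float(self.r[self.index_of(id1), self.index_of(id2)] ** 2)


@dataclass
class AlleleRef:
    """Major/minor allele per SNP from a reference panel (bim-style)."""

    table: pd.DataFrame  # columns: id, minor, major

    def __post_init__(self) -> None:
        for c in ("id", "minor", "major"):
            if c not in self.table.columns:
                raise FormatError(f"allele reference missing column {c}")
        if self.table["id"].duplicated().any():
            raise FormatError("duplicate ids in allele reference")
        if (self.table["minor"].str.upper() == self.table["major"].str.upper()).any():
            raise FormatError("allele reference with identical major/minor allele")
        self.table = self.table.set_index("id", drop=False)

    def alleles(self, snp_id: str) -> tuple[str, str]:
        row = self.table.loc[snp_id]
        return row["minor"], row["major"]


@dataclass
class JoinedLocus:
    """Two studies matched on SNP id with a common effect-allele orientation.

    ``a`` and ``b`` are canonical-column DataFrames over the same id set in
    the same order; LD matrices are aligned to that order and oriented to
    study A's effect alleles. ``drop_log`` records every SNP removed during
    matching together with the reason.
    """

    a: pd.DataFrame
    b: pd.DataFrame
    ld_a: LDMatrix
    ld_b: LDMatrix
    drop_log: list[tuple[str, str]] = field(default_factory=list)
    shared_ld: bool = True

    def __post_init__(self) -> None:
        if list(self.a["id"]) != list(self.b["id"]):
            raise LocusError("study A and B id sets/orders differ")
        if list(self.a["id"]) != list(self.ld_a.ids) or list(self.a["id"]) != list(self.ld_b.ids):
            raise LocusError("LD ids not aligned to study tables")

    @property
    def ids(self) -> list[str]:
        return self.a["id"].tolist()

    def __len__(self) -> int:
        return len(self.a)


def read_sumstats(path: str | Path, column_map: Mapping[str, str] | None = None,
                  study_label: str = "A", sep: str | None = None) -> SumStats:
    """Read a delimited summary-statistics table into a validated :class:`SumStats`.

    ``column_map`` maps canonical names (``id, chrom, pos, a1, a2, beta, se,
    pvalue, maf``) to the file's column names; identity mapping by default.
    Rows violating record invariants (se <= 0, p outside (0,1], ...) are
    rejected and reported in ``validation_log`` rather than aborting the read.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    raw = pd.read_csv(path, sep=sep)
    column_map = dict(column_map or {})
    rename = {}
    for canon in CANONICAL_COLUMNS:
        src = column_map.get(canon, canon)
        if src not in raw.columns:
            raise FormatError(f"column '{src}' (for '{canon}') not found in {path.name}")
        rename[src] = canon
    df = raw.rename(columns=rename)[CANONICAL_COLUMNS].copy()
    for col in ("pos",):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("beta", "se", "pvalue", "maf"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("id", "chrom", "a1", "a2"):
        df[col] = df[col].astype(str)
    df["a1"] = df["a1"].str.upper()
    df["a2"] = df["a2"].str.upper()

    log: list[str] = []
    keep = np.ones(len(df), dtype=bool)
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            if not np.isfinite([row.beta, row.se, row.pvalue, row.maf, row.pos]).all():
                raise ValueError(f"{row.id}: non-finite or unparseable field")
            SnpRecord(row.id, row.chrom, int(row.pos), row.a1, row.a2,
                      row.beta, row.se, row.pvalue, row.maf).validate()
        except ValueError as exc:
            keep[i] = False
            log.append(f"row {i} rejected: {exc}")
    df = df.loc[keep].reset_index(drop=True)
    df["pos"] = df["pos"].astype(int)
    return SumStats(study_label=study_label, table=df, validation_log=log)


def write_sumstats(ss: SumStats, path: str | Path) -> None:
    ss.table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_ld(path: str | Path, ids: Sequence[str] | None = None) -> LDMatrix:
    """Read signed LD from a labelled square matrix or a PLINK-style long format.

    Long format requires columns ``SNP_A, SNP_B, R``; pairs absent from the
    file default to r = 0, the diagonal to 1. If ``ids`` is given the result
    is restricted and reordered to those SNPs; an id absent from the file is
    an error.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    tokens = header.replace(",", "\t").split()
    sep_guess = "," if ("," in header and "\t" not in header) else None
    if {"SNP_A", "SNP_B", "R"} <= set(tokens):
        long = pd.read_csv(path, sep=sep_guess, engine="python")
        file_ids: list[str] = []
        seen = set()
        for col in ("SNP_A", "SNP_B"):
            for s in long[col].astype(str):
                if s not in seen:
                    seen.add(s)
                    file_ids.append(s)
        # ids absent from a pair list are simply uncorrelated with everything
        use_ids = list(ids) if ids is not None else file_ids
        pos = {s: i for i, s in enumerate(use_ids)}
        n = len(use_ids)
        r = np.eye(n)
        for a, b, val in zip(long["SNP_A"].astype(str), long["SNP_B"].astype(str),
                             pd.to_numeric(long["R"])):
            if a in pos and b in pos:
                r[pos[a], pos[b]] = val
                r[pos[b], pos[a]] = val
        return LDMatrix(use_ids, r)
    square = pd.read_csv(path, sep=sep_guess or r"\s+", index_col=0,
                         float_precision="round_trip")
    mat = LDMatrix(list(square.index.astype(str)), square.to_numpy(dtype=float))
    if ids is not None:
        mat = mat.subset(list(ids))
    return mat


def write_ld(ld: LDMatrix, path: str | Path) -> None:
    """Write a labelled square LD matrix; round-trips bit-exactly via repr floats."""
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(ld.ids) + "\n")
        for i, snp in enumerate(ld.ids):
            fh.write(snp + "\t" + "\t".join(repr(float(v)) for v in ld.r[i]) + "\n")


def read_bim(path: str | Path) -> AlleleRef:
    """Read a PLINK bim file (chrom, id, cm, pos, minor, major; tab-delimited)."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "id", "cm", "pos", "minor", "major"],
                     dtype={"id": str, "minor": str, "major": str})
    return AlleleRef(df[["id", "minor", "major"]].copy())


def _reconcile(a1: str, a2: str, b1: str, b2: str) -> str | None:
    """How study B's alleles relate to study A's: 'same', 'swap', or None.

    Strand-ambiguous (palindromic) pairs are unresolvable because the strand
    complement coincides with an allele swap; they are reported as None and
    dropped by the caller rather than risking a silent sign error.
    """
    if is_palindromic(a1, a2) or is_palindromic(b1, b2):
        return None
    if (b1, b2) == (a1, a2):
        return "same"
    if (b1, b2) == (a2, a1):
        return "swap"
    cb1, cb2 = _complement(b1), _complement(b2)
    if (cb1, cb2) == (a1, a2):
        return "same"
    if (cb1, cb2) == (a2, a1):
        return "swap"
    return None


def match_studies(a: SumStats, b: SumStats, ref: AlleleRef | None = None,
                  ld_a: LDMatrix | None = None, ld_b: LDMatrix | None = None,
                  shared_ld: bool = True) -> JoinedLocus:
    """Join the two studies on SNP id with allele-orientation reconciliation.

    Output orientation matches study A. Where B's effect/other alleles are
    swapped relative to A (directly or on the opposite strand), B's beta sign
    is negated and its alleles swapped. SNPs whose allele pairs cannot be
    reconciled — including strand-ambiguous A/T and C/G SNPs — are dropped
    and logged. LD matrices are assumed oriented to study A's effect alleles.
    """
    ta = a.table.set_index("id", drop=False)
    tb = b.table.set_index("id", drop=False)
    common = [s for s in a.table["id"] if s in tb.index]
    if not common:
        raise LocusError("no SNP ids shared between studies")
    drop_log: list[tuple[str, str]] = []
    keep: list[str] = []
    flipped: dict[str, bool] = {}
    for snp in common:
        ra, rb = ta.loc[snp], tb.loc[snp]
        rel = _reconcile(ra["a1"], ra["a2"], rb["a1"], rb["a2"])
        if rel is None:
            reason = ("palindromic" if is_palindromic(ra["a1"], ra["a2"])
                      or is_palindromic(rb["a1"], rb["a2"]) else "allele_mismatch")
            drop_log.append((snp, reason))
            continue
        if ref is not None:
            try:
                minor, major = ref.alleles(snp)
            except KeyError:
                drop_log.append((snp, "absent_from_reference"))
                continue
            if {ra["a1"], ra["a2"]} != {minor.upper(), major.upper()} and \
               {ra["a1"], ra["a2"]} != {_complement(minor), _complement(major)}:
                drop_log.append((snp, "reference_allele_mismatch"))
                continue
        keep.append(snp)
        flipped[snp] = rel == "swap"
    for snp in set(a.table["id"]) - set(common):
        drop_log.append((snp, "absent_from_B"))
    for snp in set(b.table["id"]) - set(common):
        drop_log.append((snp, "absent_from_A"))
    if not keep:
        raise LocusError("no reconcilable SNPs shared between studies")

    out_a = ta.loc[keep].reset_index(drop=True)
    out_b = tb.loc[keep].reset_index(drop=True)
    flip_mask = np.array([flipped[s] for s in keep])
    out_b.loc[flip_mask, "beta"] = -out_b.loc[flip_mask, "beta"]
    # orient B's alleles to A's coding
    out_b["a1"] = out_a["a1"].to_numpy()
    out_b["a2"] = out_a["a2"].to_numpy()

    if ld_a is None:
        ld_a = LDMatrix(keep, np.eye(len(keep)))
    else:
        ld_a = ld_a.subset(keep)
    if shared_ld or ld_b is None:
        ld_b = ld_a
    else:
        ld_b = ld_b.subset(keep)
    return JoinedLocus(a=out_a, b=out_b, ld_a=ld_a, ld_b=ld_b,
                       drop_log=drop_log, shared_ld=shared_ld)
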