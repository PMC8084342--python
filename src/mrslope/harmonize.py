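"""Formation of nearly-LD-independent signal clusters from a joined locus.

The pre-processing chain is: MAF filter -> greedy LD clumping on exposure
(eQTL) p-values -> allele flipping so every cluster member is in positive LD
with an index SNP whose exposure coefficient is positive -> collapsing of
highly correlated SNPs to representatives -> greedy trimming so that cluster
key SNPs are pairwise nearly independent (r^2 below a threshold). Trimming
runs twice in the full pipeline: first keyed on clump index SNPs, later
keyed on the candidate causal SNP chosen by colocalization.

Everything here is deterministic; ties on p-value break by genomic position.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import JoinedLocus, LDMatrix

DEFAULT_MAF = 0.01
DEFAULT_CLUMP_P1 = 0.001
DEFAULT_CLUMP_P2 = 1.0
DEFAULT_CLUMP_R2 = 0.1
DEFAULT_CLUMP_KB = 500
DEFAULT_COLLAPSE_R = 0.95
DEFAULT_TRIM_R2 = 0.05


class NoSignalError(ValueError):
    """No SNP passes the clumping index p-value threshold."""


@dataclass
class SignalCluster:
    """One clump: an index SNP plus its correlated members, both studies' records,
    and the signed sub-LD matrix over the members (oriented to study A alleles).

    ``key_id`` is the SNP used for across-cluster r^2 checks: the clump index
    initially, the colocalization candidate after the colocalization step.
    ``collapsed`` maps each representative to the members it absorbed.
    """

    index_id: str
    a: pd.DataFrame
    b: pd.DataFrame
    ld: LDMatrix
    key_id: str = ""
    collapsed: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.key_id:
            self.key_id = self.index_id
        ids = list(self.a["id"])
        if ids != list(self.b["id"]) or ids != list(self.ld.ids):
            raise ValueError("cluster member tables and LD not aligned")
        if self.index_id not in ids:
            raise ValueError("index SNP not among cluster members")

    @property
    def ids(self) -> list[str]:
        return self.a["id"].tolist()

    def __len__(self) -> int:
        return len(self.a)

    @property
    def index_pvalue(self) -> float:
        return float(self.a.loc[self.a["id"] == self.index_id, "pvalue"].iloc[0])

    def key_pvalue(self) -> float:
        return float(self.a.loc[self.a["id"] == self.key_id, "pvalue"].iloc[0])


def filter_maf(locus: JoinedLocus, threshold: float = DEFAULT_MAF) -> JoinedLocus:
    """Drop SNPs with MAF below ``threshold`` in either study (keep maf >= threshold)."""
    keep = (locus.a["maf"].to_numpy() >= threshold) & (locus.b["maf"].to_numpy() >= threshold)
    ids = [s for s, k in zip(locus.ids, keep) if k]
    log = list(locus.drop_log) + [(s, "maf_below_threshold")
                                  for s, k in zip(locus.ids, keep) if not k]
    a = locus.a.loc[keep].reset_index(drop=True)
    b = locus.b.loc[keep].reset_index(drop=True)
    if not ids:
        # empty loci are permitted; caller inspects the drop log
        return JoinedLocus(a=a, b=b, ld_a=LDMatrix([], np.empty((0, 0))),
                           ld_b=LDMatrix([], np.empty((0, 0))),
                           drop_log=log, shared_ld=locus.shared_ld)
    ld_a = locus.ld_a.subset(ids)
    ld_b = ld_a if locus.shared_ld else locus.ld_b.subset(ids)
    return JoinedLocus(a=a, b=b, ld_a=ld_a, ld_b=ld_b, drop_log=log,
                       shared_ld=locus.shared_ld)


def _order_by_p(df: pd.DataFrame, mask: np.ndarray) -> list[int]:
    """Row indices under ``mask`` sorted by (pvalue, pos) ascending."""
    idx = np.flatnonzero(mask)
    keys = list(zip(df["pvalue"].to_numpy()[idx], df["pos"].to_numpy()[idx]))
    return [int(i) for _, i in sorted(zip(keys, idx))]


def clump(locus: JoinedLocus, p1: float = DEFAULT_CLUMP_P1, p2: float = DEFAULT_CLUMP_P2,
          r2: float = DEFAULT_CLUMP_R2, kb: int = DEFAULT_CLUMP_KB) -> list[SignalCluster]:
    """Greedy LD clumping on exposure p-values, PLINK-style.

    Repeatedly the unassigned SNP with the smallest exposure p-value < ``p1``
    becomes an index; every unassigned SNP with p <= ``p2``, on the same
    chromosome within ``kb`` kilobases of the index, and with r^2 >= ``r2``
    to the index joins its cluster. Clusters are disjoint. Raises
    :class:`NoSignalError` when no SNP passes ``p1``.
    """
    a = locus.a
    n = len(a)
    pvals = a["pvalue"].to_numpy()
    pos = a["pos"].to_numpy()
    chrom = a["chrom"].to_numpy()
    r = locus.ld_a.r
    unassigned = np.ones(n, dtype=bool)
    clusters: list[SignalCluster] = []
    if not (pvals < p1).any():
        raise NoSignalError(f"no SNP with exposure p < {p1}")
    while True:
        eligible = unassigned & (pvals < p1)
        if not eligible.any():
            break
        index = _order_by_p(a, eligible)[0]
        members = (unassigned & (pvals <= p2) & (chrom == chrom[index])
                   & (np.abs(pos - pos[index]) <= kb * 1000)
                   & (r[index] ** 2 >= r2))
        members[index] = True
        midx = np.flatnonzero(members)
        ids = a["id"].to_numpy()[midx].tolist()
        clusters.append(SignalCluster(
            index_id=a["id"].iloc[index],
            a=a.iloc[midx].reset_index(drop=True),
            b=locus.b.iloc[midx].reset_index(drop=True),
            ld=locus.ld_a.subset(ids),
        ))
        unassigned[midx] = False
    return clusters


def read_clumped(path, locus: JoinedLocus) -> list[SignalCluster]:
    """Build signal clusters from a pre-computed PLINK ``.clumped`` report.

    Parses the whitespace-delimited table's ``SNP`` (index) and ``SP2``
    (member list, entries like ``rs123(1)``, or ``NONE``) columns; members
    absent from the joined locus are ignored. An alternative to internal
    clumping when clumps were produced externally.
    """
    table = pd.read_csv(path, sep=r"\s+")
    for col in ("SNP", "SP2"):
        if col not in table.columns:
            raise ValueError(f"clumped file missing column {col}")
    id_pos = {s: i for i, s in enumerate(locus.ids)}
    clusters: list[SignalCluster] = []
    for row in table.itertuples(index=False):
        index_id = str(row.SNP)
        if index_id not in id_pos:
            continue
        members = [index_id]
        sp2 = str(row.SP2)
        if sp2 and sp2.upper() != "NONE":
            for entry in sp2.split(","):
                snp = entry.strip().split("(")[0]
                if snp in id_pos and snp not in members:
                    members.append(snp)
        midx = sorted(id_pos[s] for s in members)
        ids = [locus.ids[i] for i in midx]
        clusters.append(SignalCluster(
            index_id=index_id,
            a=locus.a.iloc[midx].reset_index(drop=True),
            b=locus.b.iloc[midx].reset_index(drop=True),
            ld=locus.ld_a.subset(ids)))
    return clusters


def flip_to_index(cluster: SignalCluster) -> SignalCluster:
    """Orient every member to be in positive LD with an index SNP whose
    exposure coefficient is positive.

    If the index exposure beta is negative the index itself is flipped first
    (both study betas negated, alleles swapped, LD row/column re-signed);
    then every member negatively correlated with the index is flipped the
    same way. Idempotent: a second application changes nothing.
    """
    a = cluster.a.copy()
    b = cluster.b.copy()
    r = cluster.ld.r.copy()
    ids = cluster.ids
    iidx = ids.index(cluster.index_id)

    def _flip(i: int) -> None:
        for df in (a, b):
            df.iloc[i, df.columns.get_loc("beta")] = -df.iloc[i]["beta"]
            a1 = df.iloc[i]["a1"]
            df.iloc[i, df.columns.get_loc("a1")] = df.iloc[i]["a2"]
            df.iloc[i, df.columns.get_loc("a2")] = a1
        r[i, :] *= -1
        r[:, i] *= -1
        r[i, i] = 1.0

    if a.iloc[iidx]["beta"] < 0:
        _flip(iidx)
    for i in range(len(ids)):
        if i != iidx and r[iidx, i] < 0:
            _flip(i)
    return replace(cluster, a=a, b=b, ld=LDMatrix(ids, r))


def collapse_correlated(cluster: SignalCluster,
                        r_threshold: float = DEFAULT_COLLAPSE_R) -> SignalCluster:
    """Collapse highly correlated SNPs to representatives.

    Seeds are taken in ascending exposure p-value order (position breaks
    ties); each seed absorbs every still-unassigned SNP with signed r >
    ``r_threshold`` to it and becomes the group representative. Only
    representatives are carried forward; ``collapsed`` records the groups.
    """
    a = cluster.a
    n = len(a)
    r = cluster.ld.r
    unassigned = np.ones(n, dtype=bool)
    groups: dict[str, list[str]] = {}
    reps: list[int] = []
    ids = np.array(cluster.ids)
    while unassigned.any():
        seed = _order_by_p(a, unassigned)[0]
        absorbed = unassigned & (r[seed] > r_threshold)
        absorbed[seed] = True
        groups[ids[seed]] = ids[np.flatnonzero(absorbed)].tolist()
        reps.append(seed)
        unassigned[absorbed] = False
    reps = sorted(reps)  # keep genomic order of representatives
    rep_ids = ids[reps].tolist()
    index_id = cluster.index_id if cluster.index_id in rep_ids else rep_ids[
        int(np.argmin(cluster.a.iloc[reps]["pvalue"].to_numpy()))]
    # the clump index has the smallest p so it always seeds its own group
    return replace(cluster,
                   index_id=index_id,
                   key_id=index_id if cluster.key_id == cluster.index_id else cluster.key_id,
                   a=cluster.a.iloc[reps].reset_index(drop=True),
                   b=cluster.b.iloc[reps].reset_index(drop=True),
                   ld=cluster.ld.subset(rep_ids),
                   collapsed=groups)


def trim_clusters(clusters: list[SignalCluster], ld: LDMatrix,
                  r2_max: float = DEFAULT_TRIM_R2) -> list[SignalCluster]:
    """Greedy trimming so all pairwise key-SNP r^2 are below ``r2_max``.

    Clusters are ranked by key-SNP exposure p-value ascending (stronger
    signal first); a cluster is kept iff its key SNP has r^2 < ``r2_max``
    with the key SNP of every previously kept cluster.
    """
    order = sorted(range(len(clusters)),
                   key=lambda i: (clusters[i].key_pvalue(), clusters[i].a["pos"].min()))
    kept: list[int] = []
    for i in order:
        ok = all(ld.r2(clusters[i].key_id, clusters[j].key_id) < r2_max for j in kept)
        if ok:
            kept.append(i)
    return [clusters[i] for i in sorted(kept)]
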