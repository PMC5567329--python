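"""Iterative gene-pool accretion and the core/dispensable/strain-specific
partition.

The pan-genome is built by seeding a gene pool with every gene of a reference
strain, then processing the remaining strains one at a time: each query gene
is searched against the pool, and if it is homologous (by the BCR/identity
rule in :mod:`panstrep.homology`) to at least one pool gene it joins the
best-scoring matching cluster, otherwise it founds a new cluster and becomes
a new pool member.  The final pool is the pan gene pool; clusters are then
partitioned by how many strains they touch:

* **core** — present in every strain,
* **dispensable** — present in more than one but fewer than all strains,
* **strain-specific** — present in exactly one strain.
"""

from __future__ import annotations

import json
from collections import namedtuple
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from Bio import SeqIO

from .homology import (
    HomologyThresholds,
    PairwiseHit,
    ScoringScheme,
    align_pair,
    is_homologous,
    kmer_set,
    passes_prefilter,
)

__all__ = [
    "StrainGeneSet",
    "OrthologueCluster",
    "PanGenomeResult",
    "build_pan_pool",
    "partition_counts",
    "core_fraction",
    "PartitionCounts",
]


@dataclass
class StrainGeneSet:
    """All genes of one strain, as (gene_id, sequence) pairs."""

    strain_id: str
    genes: List[Tuple[str, str]]

    def __post_init__(self) -> None:
        ids = [g for g, _ in self.genes]
        if len(ids) != len(set(ids)):
            dup = sorted({g for g in ids if ids.count(g) > 1})
            raise ValueError(f"duplicate gene ids in strain {self.strain_id}: {dup[:5]}")

    def __len__(self) -> int:
        return len(self.genes)

    @classmethod
    def from_fasta(cls, path, strain_id: Optional[str] = None) -> "StrainGeneSet":
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
        if strain_id is None:
            import os

            strain_id = os.path.splitext(os.path.basename(str(path)))[0]
        return cls(strain_id=strain_id, genes=records)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for gene_id, seq in self.genes:
                fh.write(f">{gene_id}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")


@dataclass
class OrthologueCluster:
    cluster_id: str
    members: List[Tuple[str, str]]  # (strain_id, gene_id)
    founder_seq: str = ""

    @property
    def presence(self) -> frozenset:
        return frozenset(strain for strain, _ in self.members)

    @property
    def founder_gene_id(self) -> str:
        return self.members[0][1]


PartitionCounts = namedtuple("PartitionCounts", "core dispensable specific total")


@dataclass
class PanGenomeResult:
    clusters: List[OrthologueCluster]
    n_strains: int
    strain_order: List[str]
    parameters: dict = field(default_factory=dict)

    @property
    def core(self) -> List[OrthologueCluster]:
        if self.n_strains < 2:
            return []
        return [c for c in self.clusters if len(c.presence) == self.n_strains]

    @property
    def dispensable(self) -> List[OrthologueCluster]:
        return [c for c in self.clusters if 1 < len(c.presence) < self.n_strains]

    @property
    def specific(self) -> List[OrthologueCluster]:
        if self.n_strains < 2:
            return list(self.clusters)
        return [c for c in self.clusters if len(c.presence) == 1]

    def gene_count(self) -> int:
        return sum(len(c.members) for c in self.clusters)

    def presence_sets(self) -> List[frozenset]:
        return [c.presence for c in self.clusters]

    def flower_counts(self) -> dict:
        """Per-strain specific cluster counts plus the shared core count
        (the numbers of a flower plot)."""
        per_strain = {s: 0 for s in self.strain_order}
        for c in self.specific:
            (strain,) = c.presence
            per_strain[strain] += 1
        return {"core": len(self.core), "specific": per_strain}

    def write_clusters_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("cluster_id\tstrain_id\tgene_id\n")
            for c in self.clusters:
                for strain, gene in c.members:
                    fh.write(f"{c.cluster_id}\t{strain}\t{gene}\n")

    @classmethod
    def from_clusters_tsv(cls, path) -> "PanGenomeResult":
        clusters: Dict[str, OrthologueCluster] = {}
        order: List[str] = []
        with open(path) as fh:
            header = fh.readline()
            for line in fh:
                cid, strain, gene = line.rstrip("\n").split("\t")
                if cid not in clusters:
                    clusters[cid] = OrthologueCluster(cid, [])
                clusters[cid].members.append((strain, gene))
                if strain not in order:
                    order.append(strain)
        return cls(list(clusters.values()), n_strains=len(order), strain_order=order)

    def write_summary_json(self, path) -> None:
        counts = partition_counts(self)
        payload = {
            "n_strains": self.n_strains,
            "strain_order": self.strain_order,
            "clusters": counts.total,
            "genes": self.gene_count(),
            "core": counts.core,
            "dispensable": counts.dispensable,
            "specific": counts.specific,
            "core_fraction_pct": core_fraction(counts.core, counts.total) if counts.total else None,
            "parameters": self.parameters,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def write_flower_tsv(self, path) -> None:
        flower = self.flower_counts()
        with open(path, "w") as fh:
            fh.write("strain_id\tspecific_clusters\tcore_clusters\n")
            for strain in self.strain_order:
                fh.write(f"{strain}\t{flower['specific'][strain]}\t{flower['core']}\n")


class _PoolEntry:
    """One pool cluster during accretion: founder sequence plus its k-mer set."""

    __slots__ = ("cluster", "seqs", "kmers")

    def __init__(self, cluster: OrthologueCluster, seq: str, k: int):
        self.cluster = cluster
        self.seqs = [seq]
        self.kmers = [kmer_set(seq, k)]

    def add_member(self, seq: str, k: int, track: bool) -> None:
        if track:
            self.seqs.append(seq)
            self.kmers.append(kmer_set(seq, k))


def build_pan_pool(
    strains: Sequence[StrainGeneSet],
    thresholds: Optional[HomologyThresholds] = None,
    scoring: Optional[ScoringScheme] = None,
    search_all_members: bool = False,
    prefilter: bool = True,
) -> PanGenomeResult:
    """Run the accretion algorithm over ``strains`` (first strain = reference).

    The pool is initialised with every reference gene as a singleton cluster.
    Each subsequent strain's genes are searched against the pool; a gene joins
    the best-scoring homologous cluster (ties broken by founder gene id) or
    founds a new cluster.  Cluster representatives are their founding genes
    unless ``search_all_members`` is set, in which case every member is a
    search target.
    """
    if not strains:
        raise ValueError("at least one strain is required")
    ids = [s.strain_id for s in strains]
    if len(ids) != len(set(ids)):
        raise ValueError(f"duplicate strain_id in input: {sorted(set(i for i in ids if ids.count(i) > 1))}")
    scoring = scoring or ScoringScheme.nucleotide()
    thresholds = thresholds or HomologyThresholds.for_alphabet(scoring.alphabet)
    k = scoring.prefilter_k

    pool: List[_PoolEntry] = []
    counter = 0

    def new_cluster(strain_id: str, gene_id: str, seq: str) -> None:
        nonlocal counter
        counter += 1
        cluster = OrthologueCluster(f"C{counter:05d}", [(strain_id, gene_id)], founder_seq=seq)
        pool.append(_PoolEntry(cluster, seq, k))

    reference = strains[0]
    for gene_id, seq in reference.genes:
        new_cluster(reference.strain_id, gene_id, seq)

    for strain in strains[1:]:
        for gene_id, seq in strain.genes:
            gene_kmers = kmer_set(seq, k)
            best: Optional[Tuple[float, str, _PoolEntry]] = None
            for entry in pool:
                hit = _best_hit_against_entry(
                    seq, gene_id, gene_kmers, entry, scoring, thresholds, prefilter
                )
                if hit is None:
                    continue
                key = (-hit.score, hit.subject_id)
                if best is None or key < (-best[0], best[1]):
                    best = (hit.score, hit.subject_id, entry)
            if best is None:
                new_cluster(strain.strain_id, gene_id, seq)
            else:
                entry = best[2]
                entry.cluster.members.append((strain.strain_id, gene_id))
                entry.add_member(seq, k, search_all_members)

    params = {
        "bcr_min": thresholds.bcr_min,
        "identity_min": thresholds.identity_min,
        "min_len": thresholds.min_len,
        "alphabet": scoring.alphabet,
        "search_all_members": search_all_members,
        "prefilter": prefilter,
        "strain_order": ids,
    }
    return PanGenomeResult(
        clusters=[e.cluster for e in pool],
        n_strains=len(strains),
        strain_order=ids,
        parameters=params,
    )


def _best_hit_against_entry(
    seq: str,
    gene_id: str,
    gene_kmers: frozenset,
    entry: _PoolEntry,
    scoring: ScoringScheme,
    thresholds: HomologyThresholds,
    prefilter: bool,
) -> Optional[PairwiseHit]:
    best: Optional[PairwiseHit] = None
    member_ids = [gid for _, gid in entry.cluster.members]
    for idx, (subject_seq, subject_kmers) in enumerate(zip(entry.seqs, entry.kmers)):
        if prefilter and not passes_prefilter(gene_kmers, subject_kmers, len(seq), len(subject_seq)):
            continue
        subject_id = member_ids[idx] if idx < len(member_ids) else entry.cluster.founder_gene_id
        hit = align_pair(seq, subject_seq, scoring, query_id=gene_id, subject_id=subject_id)
        if not is_homologous(hit, thresholds):
            continue
        if best is None or (-hit.score, hit.subject_id) < (-best.score, best.subject_id):
            best = hit
    return best


def partition_counts(result: PanGenomeResult) -> PartitionCounts:
    """Cluster counts by presence-set size (core / dispensable / specific)."""
    return PartitionCounts(
        core=len(result.core),
        dispensable=len(result.dispensable),
        specific=len(result.specific),
        total=len(result.clusters),
    )


def core_fraction(core: int, total: int) -> float:
    """Percentage of clusters that are core, rounded to one decimal."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * core / total, 1)
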