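"""Synthetic multi-strain pan-genome generator with ground truth.

Emulates a set of bacterial strains drawing genes from a shared family pool:
core families present in every strain, dispensable families present in a
proper subset of strains, and strain-specific singleton families.  Each
family has a random ancestor sequence; every member is the ancestor mutated
by i.i.d. substitutions at a configurable per-site rate, so the expected
pairwise identity between two members is available in closed form.  Paralogs
are optional extra members of a family within one strain.  The generator is
fully deterministic for a fixed seed and returns a truth table mapping every
emitted gene to its family, which downstream stages are validated against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .pangenome import StrainGeneSet

__all__ = [
    "SimulationParams",
    "TruthTable",
    "simulate_pangenome",
    "mutate_sequence",
    "random_sequence",
    "expected_pairwise_identity",
    "simulate_genome_fasta",
]

_ALPHABETS = {
    "nucleotide": "ACGT",
    "protein": "ACDEFGHIKLMNPQRSTVWY",
}


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the synthetic pan-genome.

    ``dispensable_spec`` is a list of ``(family_count, strains_present)``
    pairs: each entry adds ``family_count`` families present in exactly
    ``strains_present`` randomly chosen strains (2 <= strains_present <=
    n_strains - 1).  ``divergence`` is the per-site substitution probability
    applied independently to every member relative to its family ancestor.
    """

    n_strains: int = 9
    n_core: int = 50
    dispensable_spec: Tuple[Tuple[int, int], ...] = ()
    n_specific_per_strain: int = 5
    gene_length_range: Tuple[int, int] = (150, 3000)
    divergence: float = 0.0
    paralog_rate: float = 0.0
    alphabet: str = "nucleotide"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strains < 1:
            raise ValueError("n_strains must be >= 1")
        if self.n_core < 0:
            raise ValueError("n_core must be >= 0")
        if self.n_specific_per_strain < 0:
            raise ValueError("n_specific_per_strain must be >= 0")
        for count, present in self.dispensable_spec:
            if count < 0:
                raise ValueError("dispensable_spec family_count must be >= 0")
            if not (2 <= present <= self.n_strains - 1):
                raise ValueError(
                    "dispensable_spec strains_present must satisfy "
                    f"2 <= strains_present <= n_strains-1, got {present}"
                )
        lo, hi = self.gene_length_range
        if not (0 < lo <= hi):
            raise ValueError("gene_length_range must satisfy 0 < min <= max")
        if not (0.0 <= self.divergence < 1.0):
            raise ValueError("divergence must be in [0, 1)")
        if not (0.0 <= self.paralog_rate <= 1.0):
            raise ValueError("paralog_rate must be in [0, 1]")
        if self.alphabet not in _ALPHABETS:
            raise ValueError(f"alphabet must be one of {sorted(_ALPHABETS)}")

    @property
    def n_dispensable(self) -> int:
        return sum(count for count, _ in self.dispensable_spec)


@dataclass
class TruthTable:
    """Ground-truth gene-to-family assignment and per-family presence."""

    gene_to_family: Dict[str, Tuple[str, str]]  # gene_id -> (family_id, strain_id)
    family_presence: Dict[str, frozenset]  # family_id -> strain_ids carrying it
    n_strains: int

    def expected_partition(self) -> Tuple[int, int, int]:
        """(core, dispensable, specific) family counts implied by presence."""
        core = disp = spec = 0
        for presence in self.family_presence.values():
            n = len(presence)
            if self.n_strains >= 2 and n == self.n_strains:
                core += 1
            elif n == 1 or self.n_strains < 2:
                spec += 1
            else:
                disp += 1
        return core, disp, spec

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\tfamily_id\tstrain_id\n")
            for gene_id, (family_id, strain_id) in sorted(self.gene_to_family.items()):
                fh.write(f"{gene_id}\t{family_id}\t{strain_id}\n")


def random_sequence(length: int, rng: np.random.Generator, alphabet: str = "nucleotide") -> str:
    letters = _ALPHABETS[alphabet]
    idx = rng.integers(0, len(letters), size=length)
    return "".join(letters[i] for i in idx)


def mutate_sequence(seq: str, rate: float, seed: int, alphabet: str = "nucleotide") -> str:
    """Substitute each site independently with probability ``rate``, replacing
    it by a uniformly chosen *different* symbol of the alphabet."""
    if not (0.0 <= rate < 1.0):
        raise ValueError("rate must be in [0, 1)")
    if not seq:
        return seq
    rng = np.random.default_rng(seed)
    return _mutate(seq, rate, rng, alphabet)


def _mutate(seq: str, rate: float, rng: np.random.Generator, alphabet: str = "nucleotide") -> str:
    if rate == 0.0 or not seq:
        return seq
    letters = _ALPHABETS[alphabet]
    mask = rng.random(len(seq)) < rate
    if not mask.any():
        return seq
    out = list(seq)
    for i in np.flatnonzero(mask):
        choices = [c for c in letters if c != seq[i]]
        out[i] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def expected_pairwise_identity(divergence: float, alphabet: str = "nucleotide") -> float:
    """Expected per-site identity between two family members each mutated
    independently from the ancestor at the given rate.

    A site matches if neither copy mutated, or both mutated to the same one
    of the a-1 alternative symbols: (1-d)^2 + d^2/(a-1).
    """
    a = len(_ALPHABETS[alphabet])
    d = divergence
    return (1.0 - d) ** 2 + d * d / (a - 1)


def simulate_pangenome(params: SimulationParams) -> Tuple[List[StrainGeneSet], TruthTable]:
    """Generate strain gene sets with known family structure.

    Every core family gets one member per strain (plus optional paralogs);
    every dispensable family gets members in a random strain subset of the
    configured size; strain-specific families get a member in one strain
    only.  Gene ids follow ``strain{K}|fam{J}|copy{C}``.
    """
    rng = np.random.default_rng(params.seed)
    strain_ids = [f"strain{k}" for k in range(1, params.n_strains + 1)]
    lo, hi = params.gene_length_range

    families: List[Tuple[str, List[int]]] = []  # (family_id, strain indices)
    fam_no = 0
    for _ in range(params.n_core):
        fam_no += 1
        families.append((f"fam{fam_no:05d}", list(range(params.n_strains))))
    for count, present in params.dispensable_spec:
        for _ in range(count):
            fam_no += 1
            chosen = sorted(rng.choice(params.n_strains, size=present, replace=False).tolist())
            families.append((f"fam{fam_no:05d}", chosen))
    for k in range(params.n_strains):
        for _ in range(params.n_specific_per_strain):
            fam_no += 1
            families.append((f"fam{fam_no:05d}", [k]))

    genes_per_strain: List[List[Tuple[str, str]]] = [[] for _ in range(params.n_strains)]
    gene_to_family: Dict[str, Tuple[str, str]] = {}
    family_presence: Dict[str, frozenset] = {}

    for family_id, strain_idxs in families:
        length = int(rng.integers(lo, hi + 1))
        ancestor = random_sequence(length, rng, params.alphabet)
        family_presence[family_id] = frozenset(strain_ids[i] for i in strain_idxs)
        for i in strain_idxs:
            copies = 1
            if params.paralog_rate > 0 and rng.random() < params.paralog_rate:
                copies = 2
            for c in range(1, copies + 1):
                gene_id = f"{strain_ids[i]}|{family_id}|copy{c}"
                seq = _mutate(ancestor, params.divergence, rng, params.alphabet)
                genes_per_strain[i].append((gene_id, seq))
                gene_to_family[gene_id] = (family_id, strain_ids[i])

    strains = [
        StrainGeneSet(strain_id=strain_ids[i], genes=genes_per_strain[i])
        for i in range(params.n_strains)
    ]
    truth = TruthTable(gene_to_family, family_presence, params.n_strains)
    return strains, truth


def simulate_genome_fasta(
    strain: StrainGeneSet,
    seed: int,
    spacer_range: Tuple[int, int] = (50, 500),
    gc_spacer: Optional[float] = None,
) -> Tuple[str, List[Tuple[str, int, int]]]:
    """Concatenate a strain's genes with random intergenic spacers.

    Returns the genome sequence and GFF3-style 1-based closed gene
    coordinates as ``(gene_id, start, end)``.
    """
    rng = np.random.default_rng(seed)
    lo, hi = spacer_range
    parts: List[str] = []
    coords: List[Tuple[str, int, int]] = []
    pos = 0
    for gene_id, seq in strain.genes:
        spacer_len = int(rng.integers(lo, hi + 1))
        spacer = _random_spacer(spacer_len, rng, gc_spacer)
        parts.append(spacer)
        pos += spacer_len
        coords.append((gene_id, pos + 1, pos + len(seq)))
        parts.append(seq)
        pos += len(seq)
    tail = int(rng.integers(lo, hi + 1))
    parts.append(_random_spacer(tail, rng, gc_spacer))
    return "".join(parts), coords


def _random_spacer(length: int, rng: np.random.Generator, gc: Optional[float]) -> str:
    if gc is None:
        return random_sequence(length, rng, "nucleotide")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return "".join("ACGT"[i] for i in idx)


def write_gff3(coords: Sequence[Tuple[str, int, int]], seqid: str, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene_id, start, end in coords:
            attrs = f"ID={gene_id}"
            fh.write(f"{seqid}\tpanstrep_sim\tgene\t{start}\t{end}\t.\t+\t.\t{attrs}\n")
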