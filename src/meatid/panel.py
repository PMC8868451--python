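"""Synthetic mitochondrial 16S reference panel and in-silico PCR.

The panel emulates, at desk scale, a mitochondrial reference database: one
record per species, each a reduced-length "genome" (default 2,000 bp of
random flanking sequence) carrying exactly one copy of the universal 16S
primer sites flanking a variable insert, so that the amplified product is
186 bp.  Genus is the reporting unit of the whole pipeline; species are
kept in the taxonomy for provenance.

Coordinates are 0-based, half-open, on the forward strand of each record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seq import IUPAC, is_concrete, is_iupac, mismatches, mutate, random_dna, revcomp
from .species import MEAT_SPECIES


@dataclass(frozen=True)
class PrimerPair:
    """A universal primer pair with sequencing-adapter tails.

    ``forward_target``/``reverse_target`` are the template-binding portions
    (IUPAC codes allowed); the tails are the Nextera overhangs that end up
    read through when the insert is shorter than the read length.
    """

    forward_target: str = "GACGAGAAGACCCTATTGGAGC"
    reverse_target: str = "TCCGAGGTCRCCCCAACC"
    forward_tail: str = "tcgtcggcagcgtcagatgtgtataagagacag"
    reverse_tail: str = "gtctcgtgggctcggagatgtgtataagagacag"
    expected_product_len: int = 186

    def __post_init__(self) -> None:
        for name in ("forward_target", "reverse_target"):
            if not is_iupac(getattr(self, name)):
                raise ValueError(f"{name} contains non-IUPAC characters")

    @property
    def insert_len(self) -> int:
        """Length of the variable region between the primer-binding sites."""
        return self.expected_product_len - len(self.forward_target) - len(self.reverse_target)


#: The 16S rRNA universal mammalian primer pair used throughout.
UNIVERSAL_16S = PrimerPair()


@dataclass(frozen=True)
class ReferenceRecord:
    accession: str
    species: str
    genus: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        if self.sequence != self.sequence.upper():
            raise ValueError(f"{self.accession}: sequence must be upper-case")
        if not is_iupac(self.sequence):
            raise ValueError(f"{self.accession}: sequence contains non-IUPAC characters")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product on a reference (tails excluded).

    ``start``/``end`` are forward-strand coordinates of the product
    including both primer-binding regions; ``insert_seq`` is the product
    sequence in amplicon orientation (reverse-complemented for '-' strand).
    """

    accession: str
    start: int
    end: int
    strand: str
    insert_seq: str

    @property
    def product_len(self) -> int:
        return self.end - self.start


@dataclass
class ReferencePanel:
    records: list[ReferenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.accession in seen:
                raise ValueError(f"duplicate accession {rec.accession!r}")
            seen.add(rec.accession)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, accession: str) -> ReferenceRecord:
        return self._by_accession()[accession]

    def _by_accession(self) -> dict[str, ReferenceRecord]:
        return {rec.accession: rec for rec in self.records}

    @property
    def accessions(self) -> list[str]:
        return [rec.accession for rec in self.records]

    @property
    def taxonomy(self) -> dict[str, tuple[str, str]]:
        """accession -> (species, genus)"""
        return {rec.accession: (rec.species, rec.genus) for rec in self.records}

    @property
    def genus_map(self) -> dict[str, str]:
        return {rec.accession: rec.genus for rec in self.records}

    def accessions_for_species(self, species: str) -> list[str]:
        return [rec.accession for rec in self.records if rec.species == species]


def generate_panel(
    n_genera: int,
    species_per_genus: int = 1,
    between_genus_divergence: float = 0.15,
    within_genus_divergence: float = 0.01,
    seed: int = 0,
    genome_length: int = 2000,
    primers: PrimerPair = UNIVERSAL_16S,
    species_names: list[tuple[str, str]] | None = None,
) -> ReferencePanel:
    """Generate a synthetic reference panel with one 186-bp amplicon each.

    Every record is ``genome_length`` bases of random sequence into which a
    single amplicon is embedded at a random position: the forward primer
    site, a variable insert, then the reverse complement of the reverse
    primer (degenerate positions concretised per record).  The variable
    insert descends from one ancestral insert, mutated at
    ``between_genus_divergence`` per genus and ``within_genus_divergence``
    per species within the genus; primer sites are never mutated, so
    divergence cannot destroy amplifiability.

    ``species_names`` optionally supplies ``(species, genus)`` labels in
    genus-major order; by default synthetic labels are used.
    """
    if n_genera < 1 or species_per_genus < 1:
        raise ValueError("n_genera and species_per_genus must be >= 1")
    for div in (between_genus_divergence, within_genus_divergence):
        if not 0 <= div < 0.5:
            raise ValueError("divergence must be in [0, 0.5)")
    if genome_length < primers.expected_product_len:
        raise ValueError("genome_length shorter than the amplicon")

    rng = np.random.default_rng(seed)
    fwd = primers.forward_target.upper()
    rev_site = revcomp(primers.reverse_target.upper())  # as it appears on the template
    ancestral_insert = random_dna(rng, primers.insert_len)

    names: list[tuple[str, str]] = []
    if species_names is not None:
        if len(species_names) != n_genera * species_per_genus:
            raise ValueError("species_names length does not match panel size")
        names = list(species_names)
    else:
        for g in range(n_genera):
            genus = f"Genus{g + 1:02d}"
            for s in range(species_per_genus):
                names.append((f"{genus} sp{s + 1}", genus))

    records: list[ReferenceRecord] = []
    idx = 0
    for g in range(n_genera):
        genus_insert = mutate(ancestral_insert, between_genus_divergence, rng)
        for _s in range(species_per_genus):
            species, genus_name = names[idx]
            insert = mutate(genus_insert, within_genus_divergence, rng)
            # concretise any degenerate reverse-primer positions for this record
            site = "".join(
                c if c in "ACGT" else str(rng.choice(sorted(IUPAC[c]))) for c in rev_site
            )
            product = fwd + insert + site
            flank = genome_length - len(product)
            start = int(rng.integers(0, flank + 1))
            seq = random_dna(rng, start) + product + random_dna(rng, flank - start)
            records.append(
                ReferenceRecord(
                    accession=f"REF{idx + 1:04d}", species=species,
                    genus=genus_name, sequence=seq,
                )
            )
            idx += 1
    return ReferencePanel(records)


def meat_panel(seed: int = 0, genome_length: int = 2000, **kwargs) -> ReferencePanel:
    """The default 9-species study panel (one species per meat genus)."""
    names = [MEAT_SPECIES[c] for c in MEAT_SPECIES]
    return generate_panel(
        n_genera=len(names), species_per_genus=1, seed=seed,
        genome_length=genome_length, species_names=names, **kwargs,
    )


def insilico_pcr(
    panel: ReferencePanel,
    primers: PrimerPair = UNIVERSAL_16S,
    max_mismatch: int = 0,
    max_product_len: int = 2000,
) -> list[Amplicon]:
    """Predict PCR products by scanning both strands for primer site pairs.

    A product is any forward-primer match followed, within
    ``max_product_len``, by a match of the reverse complement of the
    reverse primer.  Matching is IUPAC-aware on the primer side only and
    allows up to ``max_mismatch`` mismatches per site.  References with no
    site pair simply contribute no amplicon (they are non-amplifiable, not
    an error).
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    fwd = primers.forward_target.upper()
    rev_rc = revcomp(primers.reverse_target.upper())
    out: list[Amplicon] = []
    for rec in panel:
        for strand in "+-":
            seq = rec.sequence if strand == "+" else revcomp(rec.sequence)
            fwd_sites = _scan(seq, fwd, max_mismatch)
            rev_sites = _scan(seq, rev_rc, max_mismatch)
            for f in fwd_sites:
                for r in rev_sites:
                    end = r + len(rev_rc)
                    plen = end - f
                    if f + len(fwd) <= r and plen <= max_product_len:
                        if strand == "+":
                            start, stop = f, end
                        else:  # map back to forward-strand coordinates
                            start, stop = rec.length - end, rec.length - f
                        out.append(
                            Amplicon(
                                accession=rec.accession, start=start, end=stop,
                                strand=strand, insert_seq=seq[f:end],
                            )
                        )
    return out


def _scan(seq: str, primer: str, max_mismatch: int) -> list[int]:
    """All start positions where ``primer`` matches with <= max_mismatch."""
    k = len(primer)
    if max_mismatch == 0 and is_concrete(primer):
        hits, pos = [], seq.find(primer)
        while pos != -1:
            hits.append(pos)
            pos = seq.find(primer, pos + 1)
        return hits
    return [i for i in range(len(seq) - k + 1) if mismatches(primer, seq[i : i + k]) <= max_mismatch]


def amplicon_table(amplicons: list[Amplicon]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "accession": a.accession, "start": a.start, "end": a.end,
                "strand": a.strand, "product_len": a.product_len,
            }
            for a in amplicons
        ],
        columns=["accession", "start", "end", "strand", "product_len"],
    )


# ---------------------------------------------------------------------------
# I/O: FASTA + taxonomy TSV (columns: accession, species, genus)

def write_fasta(panel: ReferencePanel, path) -> None:
    records = [
        SeqRecord(Seq(rec.sequence), id=rec.accession, description="")
        for rec in panel
    ]
    SeqIO.write(records, str(path), "fasta")


def write_taxonomy(panel: ReferencePanel, path) -> None:
    pd.DataFrame(
        [{"accession": r.accession, "species": r.species, "genus": r.genus} for r in panel]
    ).to_csv(path, sep="\t", index=False)


def read_taxonomy(path) -> dict[str, tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"accession", "species", "genus"}
    if not required.issubset(df.columns):
        raise ValueError(f"taxonomy file must have columns {sorted(required)}")
    if df["accession"].duplicated().any():
        dup = df["accession"][df["accession"].duplicated()].iloc[0]
        raise ValueError(f"duplicate accession {dup!r} in taxonomy")
    return {row.accession: (row.species, row.genus) for row in df.itertuples()}


def read_fasta(path, taxonomy: dict[str, tuple[str, str]] | None = None) -> ReferencePanel:
    """Read a reference FASTA, optionally joining a taxonomy map.

    Duplicate accessions and non-IUPAC sequence characters are hard
    errors; so is a record without a taxonomy entry (when taxonomy is
    given) or a taxonomy entry without a record.
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate accession {rec.id!r} in FASTA")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if taxonomy is not None:
            if rec.id not in taxonomy:
                raise ValueError(f"accession {rec.id!r} missing from taxonomy")
            species, genus = taxonomy[rec.id]
        else:
            species = genus = ""
        records.append(ReferenceRecord(rec.id, species, genus, seq))
    if taxonomy is not None:
        unknown = set(taxonomy) - seen
        if unknown:
            raise ValueError(f"taxonomy rows for absent accessions: {sorted(unknown)}")
    return ReferencePanel(records)


def load_panel(fasta_path, taxonomy_path) -> ReferencePanel:
    return read_fasta(fasta_path, read_taxonomy(taxonomy_path))
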