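"""Paired-end MiSeq-style amplicon read simulator.

Reads are 2 x 300 bp drawn from the 186-bp 16S amplicon of each source
reference: read 1 starts at the amplicon 5' end, read 2 at the 3' end
(reverse complement).  Because the insert is shorter than the read, every
read runs through the full insert, then the opposing Nextera adapter tail,
then random filler bases.  Substitution errors are i.i.d. per base;
quality means decay along the cycle.  Base qualities and the substitution
process are independent (qualities model the instrument's confidence
profile, not the realised errors).

Mixture designs state DNA proportions; reads are drawn multinomially, so
DNA proportion equals expected read proportion.  An optional per-species
amplification-efficiency multiplier allows PCR-bias experiments; the
default multiplier of 1.0 asserts no bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .panel import Amplicon, PrimerPair, ReferencePanel, UNIVERSAL_16S
from .seq import revcomp
from .species import MEAT_SPECIES, genus_of_common, resolve_species

READ_LEN = 300

_ASCII = np.frombuffer(b"ACGT", dtype=np.uint8)
_LUT = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i


@dataclass(frozen=True)
class MixtureDesign:
    """A sample recipe: species and their DNA proportions.

    ``components`` may use trade names ("beef") or binomial names; they
    are resolved against the species registry and, at simulation time,
    against the panel taxonomy.  ``label`` is the species declared on the
    (virtual) product label, if any.
    """

    sample_id: str
    components: tuple[tuple[str, float], ...]
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("components must be non-empty")
        total = sum(p for _, p in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.sample_id}: proportions sum to {total}, not 1")

    @property
    def expected_genus_pct(self) -> dict[str, float]:
        """Design proportions aggregated to genus level, in percent."""
        out: dict[str, float] = {}
        for name, prop in self.components:
            genus = genus_of_common(name)
            if genus is None:
                genus = resolve_species(name).split()[0]
            out[genus] = out.get(genus, 0.0) + 100.0 * prop
        return out

    @property
    def declared_genus(self) -> str | None:
        if self.label is None:
            return None
        genus = genus_of_common(self.label)
        return genus if genus is not None else resolve_species(self.label).split()[0]


@dataclass
class ReadSet:
    """Paired reads with qualities and (optional) ground-truth provenance."""

    sample_id: str
    ids: list[str] = field(default_factory=list)
    seq1: list[str] = field(default_factory=list)
    qual1: list[str] = field(default_factory=list)
    seq2: list[str] = field(default_factory=list)
    qual2: list[str] = field(default_factory=list)
    truth: list[str | None] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.ids)

    def subset(self, indices) -> "ReadSet":
        take = lambda xs: [xs[i] for i in indices]  # noqa: E731
        return ReadSet(
            self.sample_id, take(self.ids), take(self.seq1), take(self.qual1),
            take(self.seq2), take(self.qual2), take(self.truth),
        )


@dataclass(frozen=True)
class QualityProfile:
    """Per-cycle mean Phred quality: linear-power decay start -> end."""

    q_start: float = 37.0
    q_end: float = 25.0
    shape: float = 1.0
    noise_sd: float = 2.0
    q_floor: int = 2
    q_ceil: int = 40

    def means(self, length: int) -> np.ndarray:
        c = np.arange(length) / max(length - 1, 1)
        return self.q_end + (self.q_start - self.q_end) * (1.0 - c) ** self.shape


def _resolve_components(
    panel: ReferencePanel,
    amplicon_by_acc: dict[str, Amplicon],
    design: MixtureDesign,
    bias: dict[str, float] | None,
) -> tuple[list[str], np.ndarray]:
    """Expand species proportions to amplifiable-accession probabilities."""
    accs: list[str] = []
    weights: list[float] = []
    for name, prop in design.components:
        species = resolve_species(name)
        hits = [a for a in panel.accessions_for_species(species) if a in amplicon_by_acc]
        if not hits:
            raise ValueError(
                f"{design.sample_id}: species {species!r} has no amplifiable reference"
            )
        mult = (bias or {}).get(species, 1.0)
        for acc in hits:
            accs.append(acc)
            weights.append(prop * mult / len(hits))
    w = np.asarray(weights, dtype=float)
    return accs, w / w.sum()


def simulate_sample(
    panel: ReferencePanel,
    amplicons: list[Amplicon],
    design: MixtureDesign,
    n_pairs: int,
    error_rate: float = 0.002,
    quality_profile: QualityProfile = QualityProfile(),
    seed: int = 0,
    read_len: int = READ_LEN,
    primers: PrimerPair = UNIVERSAL_16S,
    amplification_bias: dict[str, float] | None = None,
) -> ReadSet:
    """Simulate one sample's paired FASTQ reads; deterministic per seed."""
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    amplicon_by_acc = {a.accession: a for a in amplicons}
    accs, probs = _resolve_components(panel, amplicon_by_acc, design, amplification_bias)

    rng = np.random.default_rng(seed)
    src = rng.choice(len(accs), size=n_pairs, p=probs)

    tail1 = revcomp(primers.reverse_tail).upper()   # read 1 runs into the reverse tail
    tail2 = revcomp(primers.forward_tail).upper()   # read 2 runs into the forward tail
    tmpl1, tmpl2 = [], []
    for acc in accs:
        ins = amplicon_by_acc[acc].insert_seq
        tmpl1.append(_encode((ins + tail1)[:read_len]))
        tmpl2.append(_encode((revcomp(ins) + tail2)[:read_len]))

    m1 = rng.integers(0, 4, size=(n_pairs, read_len), dtype=np.uint8)
    m2 = rng.integers(0, 4, size=(n_pairs, read_len), dtype=np.uint8)
    for a_idx in range(len(accs)):
        rows = np.nonzero(src == a_idx)[0]
        if rows.size:
            m1[rows[:, None], np.arange(tmpl1[a_idx].size)] = tmpl1[a_idx]
            m2[rows[:, None], np.arange(tmpl2[a_idx].size)] = tmpl2[a_idx]

    for m in (m1, m2):
        if error_rate > 0:
            hit = rng.random(m.shape) < error_rate
            m[hit] = (m[hit] + rng.integers(1, 4, size=int(hit.sum()), dtype=np.uint8)) % 4

    means = quality_profile.means(read_len)
    quals = []
    for _ in range(2):
        q = np.rint(means + rng.normal(0.0, quality_profile.noise_sd, size=(n_pairs, read_len)))
        quals.append(
            np.clip(q, quality_profile.q_floor, quality_profile.q_ceil).astype(np.uint8) + 33
        )

    rs = ReadSet(design.sample_id)
    rs.truth = [accs[j] for j in src]
    rs.ids = [f"{design.sample_id}|{i}|{acc}" for i, acc in enumerate(rs.truth)]
    rs.seq1 = _rows_to_str(_ASCII[m1])
    rs.seq2 = _rows_to_str(_ASCII[m2])
    rs.qual1 = _rows_to_str(quals[0])
    rs.qual2 = _rows_to_str(quals[1])
    return rs


def _rows_to_str(matrix: np.ndarray) -> list[str]:
    width = matrix.shape[1]
    return [b.decode() for b in np.ascontiguousarray(matrix).view(f"S{width}").ravel()]


def _encode(seq: str) -> np.ndarray:
    return _LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]


# ---------------------------------------------------------------------------
# Study designs

#: Two-species DNA mixtures at 1:1 (order as listed in the study design).
MIX_1TO1 = [("pork", "beef"), ("mutton", "chevon"), ("chicken", "turkey"),
            ("ostrich", "duck"), ("beef", "kangaroo")]
#: Two-species DNA mixtures at 9:1; the pork/beef mixture appears twice.
MIX_9TO1 = [("pork", "beef"), ("pork", "beef"), ("mutton", "chevon"),
            ("chevon", "mutton"), ("chicken", "duck"), ("duck", "chicken"),
            ("ostrich", "duck"), ("duck", "ostrich")]


def build_paper_designs(
    pure_replicates: int = 2, mixture_replicates: int = 3
) -> list[MixtureDesign]:
    """The validation experiment's sample sheet.

    Nine pure controls sequenced in duplicate (18 samples), five 1:1 and
    eight 9:1 two-species mixtures in triplicate (39 samples).
    """
    designs: list[MixtureDesign] = []
    for name in MEAT_SPECIES:
        for r in range(1, pure_replicates + 1):
            designs.append(
                MixtureDesign(f"pure_{name}_r{r}", ((name, 1.0),), label=name)
            )
    for i, (a, b) in enumerate(MIX_1TO1, start=1):
        for r in range(1, mixture_replicates + 1):
            designs.append(
                MixtureDesign(f"mix11_{i:02d}_{a}_{b}_r{r}", ((a, 0.5), (b, 0.5)))
            )
    for i, (a, b) in enumerate(MIX_9TO1, start=1):
        for r in range(1, mixture_replicates + 1):
            designs.append(
                MixtureDesign(f"mix91_{i:02d}_{a}_{b}_r{r}", ((a, 0.9), (b, 0.1)))
            )
    return designs


# ---------------------------------------------------------------------------
# FASTQ I/O (Phred+33)

def write_fastq(readset: ReadSet, path_r1, path_r2) -> None:
    for path, seqs, quals, mate in (
        (path_r1, readset.seq1, readset.qual1, 1),
        (path_r2, readset.seq2, readset.qual2, 2),
    ):
        records = []
        for rid, seq, qual in zip(readset.ids, seqs, quals):
            rec = SeqRecord(Seq(seq), id=f"{rid}/{mate}", description="")
            rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in qual]
            records.append(rec)
        SeqIO.write(records, str(path), "fastq")


def read_fastq(path_r1, path_r2, sample_id: str | None = None) -> ReadSet:
    """Read a mate pair of FASTQ files; mate order must correspond."""
    r1 = _parse_fastq(path_r1)
    r2 = _parse_fastq(path_r2)
    if len(r1) != len(r2):
        raise ValueError(f"mate-count mismatch: {len(r1)} in R1 vs {len(r2)} in R2")
    rs = ReadSet(sample_id or "")
    for (id1, s1, q1), (_id2, s2, q2) in zip(r1, r2):
        rid = id1[:-2] if id1.endswith(("/1", "/2")) else id1
        parts = rid.split("|")
        rs.ids.append(rid)
        rs.seq1.append(s1)
        rs.qual1.append(q1)
        rs.seq2.append(s2)
        rs.qual2.append(q2)
        rs.truth.append(parts[2] if len(parts) == 3 else None)
    if not rs.sample_id and rs.ids:
        rs.sample_id = rs.ids[0].split("|")[0]
    return rs


def _parse_fastq(path) -> list[tuple[str, str, str]]:
    out = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            out.append((rec.id, str(rec.seq), qual))
    except ValueError as exc:
        raise ValueError(
            f"{path}: malformed FASTQ near record {len(out) + 1} (line ~{4 * len(out) + 1}): {exc}"
        ) from exc
    return out
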