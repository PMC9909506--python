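"""Seeded generator of ground-truthed toy genomes.

Each chromosome is laid out as

    5' telomere array + random sequence + one centromeric satellite
    array + random sequence + 3' telomere array

with every planted feature recorded in a :class:`TruthManifest` that is
re-derivable by direct string inspection of the emitted FASTA.  The
random background is i.i.d. uniform over ACGT, which keeps the
no-false-positive expectations of the k-mer mapper, the tandem-array
detector and the telomere scan analytically calculable.  Haplotype 2 is
derived from haplotype 1 by per-base substitutions and short indels
outside the telomere arrays.

Divergence model: per-base substitution at the stated rate; 1-bp indels
at one tenth of that rate.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from .pairwise import revcomp
from .seqio import SeqRecord

__all__ = [
    "SimParams", "TelomereTruth", "CentromereTruth", "ChromTruth",
    "ContigTruth", "GapTruth", "TruthManifest",
    "generate_genome", "fragment_into_contigs",
    "make_gapped_object_and_donors", "mutate_sequence", "random_sequence",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimParams:
    """Study conditions for the generator.

    Defaults emulate the genome features the toolkit characterizes:
    7-bp telomeric units (CCCATTT on the 5' arm, TTTAGGG on the 3' arm)
    in arrays of 400 units (2.8 kb, inside the observed 0.5-16 kb range);
    a single 300-kb centromeric array per chromosome built from a 153-bp
    monomer at 2% per-base divergence between copies.
    """

    telomere_unit_5p: str = "CCCATTT"
    telomere_unit_3p: str = "TTTAGGG"
    telomere_units_5p: int = 400
    telomere_units_3p: int = 400
    monomer_lengths: tuple[int, ...] = (153,)
    centromere_span: int = 300_000
    divergence: float = 0.02
    mixture_fractions: tuple[float, ...] | None = None
    hor_unit: int = 1  # >1: that many distinct monomers per repeating unit
    cen_position: float = 0.5
    hap2_snp_rate: float = 0.002
    hap2_indel_rate: float = 0.0002


@dataclass
class TelomereTruth:
    chrom: str
    start: int
    end: int
    unit: str
    unit_count: int


@dataclass
class CentromereTruth:
    chrom: str
    start: int
    end: int
    monomers: list[str]
    monomer_lengths: list[int]
    fractions: list[float]
    divergence: float
    hor_unit: int


@dataclass
class ChromTruth:
    chrom: str
    length: int
    telomere_5p: TelomereTruth
    telomere_3p: TelomereTruth
    centromere: CentromereTruth


@dataclass
class ContigTruth:
    contig_id: str
    chrom: str
    start: int
    end: int
    orientation: str
    rank: int  # position of the fragment along its chromosome


@dataclass
class GapTruth:
    gap_id: str
    chrom: str
    start: int
    end: int
    hidden_seq: str
    donor_id: str
    donor_strand: str


@dataclass
class TruthManifest:
    seed: int
    haplotypes: dict[str, dict[str, ChromTruth]] = field(default_factory=dict)
    contigs: dict[str, list[ContigTruth]] = field(default_factory=dict)
    gaps: dict[str, list[GapTruth]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def random_sequence(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def mutate_sequence(seq: str, rate: float, rng: np.random.Generator,
                    indel_rate: float | None = None) -> str:
    """Substitute bases at ``rate`` and apply 1-bp indels at
    ``indel_rate`` (default rate/10)."""
    if rate == 0 and not indel_rate:
        return seq
    if indel_rate is None:
        indel_rate = rate / 10.0
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    n = len(arr)
    # substitutions: shift by 1-3 positions in the base ring so the new
    # base always differs from the old one
    sub = rng.random(n) < rate
    if sub.any():
        code = np.zeros(n, dtype=np.uint8)
        for i, b in enumerate(_BASES):
            code[arr == b] = i
        shift = rng.integers(1, 4, int(sub.sum())).astype(np.uint8)
        code[sub] = (code[sub] + shift) % 4
        arr = _BASES[code]
    if indel_rate > 0:
        out = []
        pos = 0
        events = np.nonzero(rng.random(n) < indel_rate)[0]
        kinds = rng.random(len(events)) < 0.5  # True: deletion
        ins_bases = _BASES[rng.integers(0, 4, len(events))]
        for ev, is_del, ib in zip(events, kinds, ins_bases):
            out.append(arr[pos:ev].tobytes())
            if is_del:
                pos = ev + 1
            else:
                out.append(bytes([ib]) + arr[ev:ev + 1].tobytes())
                pos = ev + 1
        out.append(arr[pos:].tobytes())
        return b"".join(out).decode()
    return arr.tobytes().decode()


def _build_centromere(rng: np.random.Generator, params: SimParams
                      ) -> tuple[str, list[str], list[float]]:
    """Return (array sequence, monomer list, base fractions)."""
    monomers = [random_sequence(rng, L) for L in params.monomer_lengths]
    span = params.centromere_span
    div = params.divergence
    if params.hor_unit > 1:
        # higher-order unit of several distinct monomers, repeated
        # head-to-tail
        unit_monomers = [
            random_sequence(rng, params.monomer_lengths[
                i % len(params.monomer_lengths)])
            for i in range(params.hor_unit)
        ]
        unit = "".join(unit_monomers)
        copies = max(2, span // len(unit))
        parts = [mutate_sequence(unit, div, rng) for _ in range(copies)]
        return "".join(parts), unit_monomers, \
            [1.0 / params.hor_unit] * params.hor_unit
    if params.mixture_fractions is not None:
        fr = params.mixture_fractions
        if len(fr) != len(monomers) or abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError("mixture_fractions must match monomer_lengths "
                             "and sum to 1")
        blocks = []
        for mono, f in zip(monomers, fr):
            copies = max(2, int(span * f) // len(mono))
            blocks.append("".join(
                mutate_sequence(mono, div, rng) for _ in range(copies)))
        return "".join(blocks), monomers, list(fr)
    mono = monomers[0]
    copies = max(2, span // len(mono))
    arr = "".join(mutate_sequence(mono, div, rng) for _ in range(copies))
    return arr, monomers, [1.0]


def generate_genome(n_chroms: int, chrom_len: int,
                    params: SimParams | None = None, seed: int = 0
                    ) -> tuple[list[SeqRecord], list[SeqRecord],
                               TruthManifest]:
    """Generate a two-haplotype toy genome with planted telomeres,
    centromeres and a ground-truth manifest.  Byte-identical for
    identical (params, seed)."""
    params = params or SimParams()
    rng = np.random.default_rng(seed)
    manifest = TruthManifest(seed=seed)
    manifest.haplotypes = {"hap1": {}, "hap2": {}}
    hap1: list[SeqRecord] = []
    hap2: list[SeqRecord] = []
    for ci in range(n_chroms):
        chrom = f"Chr{ci + 1:02d}"
        telo5 = params.telomere_unit_5p * params.telomere_units_5p
        telo3 = params.telomere_unit_3p * params.telomere_units_3p
        cen, monomers, fractions = _build_centromere(rng, params)
        interior = chrom_len - len(telo5) - len(telo3) - len(cen)
        if interior < 2:
            raise ValueError("centromere span too large for chromosome "
                             "length")
        left_pad = int(params.cen_position * interior)
        left_pad = min(max(left_pad, 1), interior - 1)
        rand1 = random_sequence(rng, left_pad)
        rand2 = random_sequence(rng, interior - left_pad)
        seq = telo5 + rand1 + cen + rand2 + telo3
        cen_start = len(telo5) + len(rand1)
        hap1.append(SeqRecord(chrom, seq))
        manifest.haplotypes["hap1"][chrom] = ChromTruth(
            chrom=chrom, length=len(seq),
            telomere_5p=TelomereTruth(chrom, 0, len(telo5),
                                      params.telomere_unit_5p,
                                      params.telomere_units_5p),
            telomere_3p=TelomereTruth(chrom, len(seq) - len(telo3),
                                      len(seq), params.telomere_unit_3p,
                                      params.telomere_units_3p),
            centromere=CentromereTruth(
                chrom, cen_start, cen_start + len(cen), monomers,
                [len(m) for m in monomers], fractions, params.divergence,
                params.hor_unit),
        )
        # haplotype 2: mutate everything between the telomere arrays
        seg1 = mutate_sequence(rand1, params.hap2_snp_rate, rng,
                               params.hap2_indel_rate)
        segc = mutate_sequence(cen, params.hap2_snp_rate, rng,
                               params.hap2_indel_rate)
        seg2 = mutate_sequence(rand2, params.hap2_snp_rate, rng,
                               params.hap2_indel_rate)
        seq2 = telo5 + seg1 + segc + seg2 + telo3
        cen2_start = len(telo5) + len(seg1)
        hap2.append(SeqRecord(chrom, seq2))
        manifest.haplotypes["hap2"][chrom] = ChromTruth(
            chrom=chrom, length=len(seq2),
            telomere_5p=TelomereTruth(chrom, 0, len(telo5),
                                      params.telomere_unit_5p,
                                      params.telomere_units_5p),
            telomere_3p=TelomereTruth(chrom, len(seq2) - len(telo3),
                                      len(seq2), params.telomere_unit_3p,
                                      params.telomere_units_3p),
            centromere=CentromereTruth(
                chrom, cen2_start, cen2_start + len(segc), monomers,
                [len(m) for m in monomers], fractions, params.divergence,
                params.hor_unit),
        )
    return hap1, hap2, manifest


def fragment_into_contigs(haplotype: Sequence[SeqRecord],
                          n_breaks: int | dict[str, int],
                          overlap: int = 0, seed: int = 0,
                          revcomp_prob: float = 0.5,
                          avoid: Sequence[tuple[str, int, int]] = (),
                          avoid_margin: int = 5000
                          ) -> tuple[list[SeqRecord], list[ContigTruth]]:
    """Cut each chromosome at clean random breakpoints, optionally with
    flanking overlap between adjacent fragments, reverse-complement a
    random subset, and shuffle.  Provenance records truth placement.

    ``avoid`` lists (chrom, start, end) regions — typically the planted
    repeat arrays — that breakpoints must stay ``avoid_margin`` bases
    clear of; a break inside a satellite array makes junction-level
    reconstruction phase-ambiguous for any aligner.
    """
    rng = np.random.default_rng(seed)
    pieces: list[tuple[str, str, int, int, str, int]] = []
    for rec in haplotype:
        nb = n_breaks[rec.id] if isinstance(n_breaks, dict) else n_breaks
        L = len(rec)
        forbidden = [(max(0, s - avoid_margin), e + avoid_margin)
                     for c, s, e in avoid if c == rec.id]
        if nb > 0 and nb >= L // 10_000:
            raise ValueError(f"too many breaks for {rec.id}")
        if nb == 0:
            bps: list[int] = []
        else:
            # resample until breakpoints are well separated and clear
            # of forbidden regions
            for _attempt in range(10_000):
                bps = sorted(rng.integers(10_000, L - 10_000, nb).tolist())
                if nb > 1 and min(np.diff(bps)) < 20_000:
                    continue
                if any(s <= b < e for b in bps for s, e in forbidden):
                    continue
                break
            else:
                raise ValueError(f"cannot place {nb} breakpoints on "
                                 f"{rec.id} outside avoided regions")
        bounds = [0] + bps + [L]
        for rank in range(len(bounds) - 1):
            s, e = bounds[rank], bounds[rank + 1]
            e_ov = min(L, e + overlap) if rank < len(bounds) - 2 else e
            seq = rec.sequence[s:e_ov]
            orient = "-" if rng.random() < revcomp_prob else "+"
            pieces.append((rec.id, seq, s, e_ov, orient, rank))
    rng.shuffle(pieces)
    contigs: list[SeqRecord] = []
    provenance: list[ContigTruth] = []
    for i, (chrom, seq, s, e, orient, rank) in enumerate(pieces):
        cid = f"ctg{i + 1:04d}"
        contigs.append(SeqRecord(cid, seq if orient == "+"
                                 else revcomp(seq)))
        provenance.append(ContigTruth(cid, chrom, s, e, orient, rank))
    return contigs, provenance


def make_gapped_object_and_donors(haplotype: Sequence[SeqRecord],
                                  n_gaps: int, gap_len: int = 5000,
                                  donor_flank: int = 2000, seed: int = 0,
                                  donor_divergence: float = 0.0,
                                  random_strand: bool = True,
                                  margin: int = 60_000,
                                  spacing: int = 100_000
                                  ) -> tuple[list[SeqRecord],
                                             list[SeqRecord],
                                             list[GapTruth]]:
    """Replace n_gaps stretches of true sequence by N runs and emit one
    spanning donor per gap (true flanks + true hidden sequence, with
    configurable divergence and strand)."""
    rng = np.random.default_rng(seed)
    gapped: list[SeqRecord] = []
    donors: list[SeqRecord] = []
    truths: list[GapTruth] = []
    # spread gaps over chromosomes round-robin
    per_chrom = [n_gaps // len(haplotype)] * len(haplotype)
    for i in range(n_gaps % len(haplotype)):
        per_chrom[i] += 1
    for rec, ng in zip(haplotype, per_chrom):
        seq = rec.sequence
        L = len(seq)
        positions: list[int] = []
        attempts = 0
        while len(positions) < ng:
            attempts += 1
            if attempts > 10_000:
                raise ValueError("cannot place gaps with the requested "
                                 "margin/spacing")
            g = int(rng.integers(margin, L - margin - gap_len))
            if all(abs(g - p) >= spacing for p in positions):
                positions.append(g)
        positions.sort()
        new_seq = seq
        for k, g in enumerate(positions, start=1):
            hidden = seq[g:g + gap_len]
            new_seq = new_seq[:g] + "N" * gap_len + new_seq[g + gap_len:]
            donor_seq = seq[g - donor_flank:g + gap_len + donor_flank]
            if donor_divergence > 0:
                donor_seq = mutate_sequence(donor_seq, donor_divergence,
                                            rng)
            strand = "+"
            if random_strand and rng.random() < 0.5:
                donor_seq = revcomp(donor_seq)
                strand = "-"
            did = f"donor_{rec.id}_{k}"
            donors.append(SeqRecord(did, donor_seq))
            truths.append(GapTruth(
                gap_id=f"{rec.id}_gap{k}", chrom=rec.id, start=g,
                end=g + gap_len, hidden_seq=hidden, donor_id=did,
                donor_strand=strand))
        gapped.append(SeqRecord(rec.id, new_seq))
    return gapped, donors, truths
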