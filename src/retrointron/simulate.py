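"""Synthetic genomes with truth-labelled retroposition and intron-gain
events.

The generator emulates the data regime the pipeline is built for:
multi-exon parent genes with canonical GT-AG introns (branch motif and
polypyrimidine tract embedded), processed retrocopies (introns spliced
out, poly(A) tail, new genomic insertion site on either strand),
sequence divergence with substitutions and short (1-30 bp) indels, and
injected intron-gain events of the three mechanism classes with known
truth labels:

* ``intronization_substitution`` — up to two base edits create GT-AG
  boundaries inside formerly exonic sequence;
* ``intronization_cryptic`` — a pre-existing GT...AG pair of the
  parental exon is marked spliced in the retrogene annotation only;
* ``insertion`` — an external sequence carrying splice boundaries is
  inserted into the retrocopy;
* ``reverse_orientation`` — the retrogene is annotated as transcribed on
  the opposite strand, with boundaries valid on that strand.

DNA-duplication decoys (parent copied *with* its introns) are also
planted so the scan's discard logic is exercised.  Output is restricted
to standard formats: genome FASTA, annotation GFF3, truth TSV (plus
parent proteins FASTA, junction-support BED12 and a repeat BED).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from retrointron.core import GeneModel, GenomicInterval, revcomp, write_fasta
from retrointron.io import Bed12Record, write_annotation, write_bed12
from retrointron.kaks import GENETIC_CODE, SENSE_CODONS

MECHANISMS = (
    "intronization_substitution",
    "intronization_cryptic",
    "insertion",
    "reverse_orientation",
)


class GenerationError(RuntimeError):
    """Raised when a configuration cannot produce a valid structure."""


class InjectionError(RuntimeError):
    """Raised when an intron-gain event cannot be placed."""


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset."""

    n_parents: int = 20
    n_retrocopies: int = 30
    n_gain_events: int = 12
    n_decoys: int = 3
    exon_count: tuple[int, int] = (5, 8)
    exon_len: tuple[int, int] = (90, 210)
    intron_len: tuple[int, int] = (70, 250)
    intergenic: tuple[int, int] = (500, 900)
    # insertion sites are effectively isolated in real genomes; keep them
    # farther apart than the flank windows the scan inspects
    retro_spacing: tuple[int, int] = (2500, 4000)
    sub_rate: float = 0.03
    indel_rate: float = 0.0005
    indel_len: tuple[int, int] = (1, 30)
    polya_len: int = 30
    new_intron_len: tuple[int, int] = (80, 200)
    compensating_indel_prob: float = 0.5
    mechanism_probs: dict = field(default_factory=lambda: {
        "intronization_substitution": 0.25,
        "intronization_cryptic": 0.25,
        "insertion": 0.25,
        "reverse_orientation": 0.25,
    })

    def validate(self) -> None:
        for name in ("sub_rate", "indel_rate", "compensating_indel_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("exon_count", "exon_len", "intron_len", "intergenic",
                     "retro_spacing", "indel_len", "new_intron_len"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name}=({lo},{hi}) has no positive support")
        if self.intron_len[0] < 40:
            raise ValueError("intron_len lower bound must be >= 40 "
                             "(room for splice signals)")
        total = sum(self.mechanism_probs.get(m, 0.0) for m in MECHANISMS)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("mechanism probabilities must sum to 1")
        if self.n_gain_events > self.n_retrocopies:
            raise ValueError("more gain events than retrocopies")


@dataclass
class TruthRecord:
    """Ground truth for one simulated retrocopy locus."""

    retro_id: str
    parent_id: str
    chrom: str
    start: int
    end: int
    strand: str                 # genomic insertion strand
    annotated_strand: str       # transcription strand of the annotation
    mechanism: str              # MECHANISMS or 'none'
    intron_start: int = -1      # genomic coords; -1 when no intron
    intron_end: int = -1
    intron_length: int = 0
    n_substitutions: int = 0
    n_edit_bases: int = 0       # targeted splice-site edits
    indels: str = ""            # 'kind@retro_pos:len;...'
    is_decoy: bool = False


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def _ppt(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(["T", "C"], n, p=[0.65, 0.35]))


def make_intron(rng: np.random.Generator, length: int) -> str:
    """Canonical intron: GT donor context, branch motif, PPT, AG."""
    if length < 40:
        raise GenerationError(f"intron length {length} too short")
    fixed = 6 + 6 + 18 + 3  # donor, branch, ppt, 'CAG'
    mid = random_seq(rng, length - fixed)
    return "GTAAGT" + mid + "ACTAAC" + _ppt(rng, 18) + "CAG"


def translate(cds: str) -> str:
    return "".join(GENETIC_CODE[cds[i:i + 3]] for i in range(0, len(cds), 3))


# ---------------------------------------------------------------------------
# parent genes
# ---------------------------------------------------------------------------

def generate_parent_gene(config: SimulationConfig, rng: np.random.Generator,
                         max_retries: int = 10) -> dict:
    """One multi-exon gene: returns the gene-region sequence plus exon
    layout (region-relative), CDS and protein.  The CDS translates with
    no internal stop and every intron has GT-AG boundaries."""
    config.validate()
    last_err: Exception | None = None
    for _ in range(max_retries):
        try:
            n_exons = int(rng.integers(config.exon_count[0],
                                       config.exon_count[1] + 1))
            lens = [int(rng.integers(config.exon_len[0], config.exon_len[1] + 1))
                    for _ in range(n_exons)]
            total = sum(lens)
            lens[-1] += (3 - total % 3) % 3
            n_codons = sum(lens) // 3
            if n_codons < 3:
                raise GenerationError("CDS too short")
            interior = [SENSE_CODONS[i] for i in
                        rng.integers(0, len(SENSE_CODONS), n_codons - 2)]
            cds = "ATG" + "".join(interior) + "TAA"
            exon_seqs = []
            off = 0
            for ln in lens:
                exon_seqs.append(cds[off:off + ln])
                off += ln
            introns = [make_intron(
                rng, int(rng.integers(config.intron_len[0],
                                      config.intron_len[1] + 1)))
                for _ in range(n_exons - 1)]
            parts, exons_rel, pos = [], [], 0
            for i, ex in enumerate(exon_seqs):
                parts.append(ex)
                exons_rel.append((pos, pos + len(ex)))
                pos += len(ex)
                if i < len(introns):
                    parts.append(introns[i])
                    pos += len(introns[i])
            return {
                "seq": "".join(parts),
                "exons_rel": exons_rel,
                "cds": cds,
                "protein": translate(cds[:-3]),
            }
        except GenerationError as exc:
            last_err = exc
    raise GenerationError(f"could not generate gene: {last_err}")


# ---------------------------------------------------------------------------
# retroposition + intron-gain injection
# ---------------------------------------------------------------------------

def _find_pairs(seq: str, donor: str, acceptor: str,
                length_range: tuple[int, int], margin: int) -> list[tuple[int, int]]:
    lo, hi = length_range
    donors = [i for i in range(margin, len(seq) - margin - lo)
              if seq[i:i + 2] == donor]
    acceptors = [j for j in range(margin + lo, len(seq) - margin)
                 if seq[j - 2:j] == acceptor]
    pairs = []
    for a in donors:
        for b in acceptors:
            if lo <= b - a <= hi:
                pairs.append((a, b))
    return pairs


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def retropose(mrna: str, config: SimulationConfig,
              rng: np.random.Generator) -> str:
    """Clean retrocopy sequence: the spliced mRNA plus a poly(A) tail
    (divergence is applied separately so event injection can protect its
    critical positions)."""
    return mrna + "A" * config.polya_len


def inject_intron_gain(retro: str, mechanism: str, config: SimulationConfig,
                       rng: np.random.Generator) -> dict:
    """Plant one intron-gain event in a clean (undiverged) retro mRNA.

    Returns the edited sequence, the intron's retro-local coordinates,
    the set of positions that must be protected from later divergence,
    any targeted edits and any compensating indel.
    """
    margin = 150
    lo, hi = config.new_intron_len
    edits: list[int] = []
    comp_indel = None

    if mechanism == "intronization_cryptic":
        pairs = _find_pairs(retro, "GT", "AG", (lo, hi), margin)
        if not pairs:
            raise InjectionError("no cryptic GT...AG pair available")
        a, b = pairs[int(rng.integers(0, len(pairs)))]
        seq = retro

    elif mechanism == "intronization_substitution":
        candidates = []
        for a in range(margin, len(retro) - margin - lo):
            d_edit = _hamming(retro[a:a + 2], "GT")
            if d_edit != 1:
                continue
            for b in range(a + lo, min(a + hi, len(retro) - margin)):
                a_edit = _hamming(retro[b - 2:b], "AG")
                if 1 <= d_edit + a_edit <= 2:
                    candidates.append((a, b))
        if not candidates:
            raise InjectionError("no near-miss splice-site pair for substitution")
        mult3 = [p for p in candidates if (p[1] - p[0]) % 3 == 0]
        want_comp = rng.random() < config.compensating_indel_prob
        pool = [p for p in candidates if (p[1] - p[0]) % 3 != 0] if want_comp \
            else mult3
        if not pool:
            pool = candidates
        a, b = pool[int(rng.integers(0, len(pool)))]
        chars = list(retro)
        for off, want in ((0, "G"), (1, "T")):
            if chars[a + off] != want:
                chars[a + off] = want
                edits.append(a + off)
        for off, want in ((-2, "A"), (-1, "G")):
            if chars[b + off] != want:
                chars[b + off] = want
                edits.append(b + off)
        seq = "".join(chars)
        if (b - a) % 3 != 0:
            # compensate: retro-side insertion restoring delta % 3 == 0
            l_ins = (b - a) % 3 + 3 * int(rng.integers(1, 6))
            p = a - int(rng.integers(10, 60))
            seq = seq[:p] + random_seq(rng, l_ins) + seq[p:]
            a += l_ins
            b += l_ins
            edits = [e + l_ins for e in edits]
            comp_indel = ("insertion", p, l_ins)

    elif mechanism == "insertion":
        length = int(rng.integers(lo, hi + 1))
        length -= length % 3  # non-frameshift by construction
        ins = make_intron(rng, length)
        p = int(rng.integers(margin, len(retro) - margin))
        seq = retro[:p] + ins + retro[p:]
        a, b = p, p + len(ins)

    elif mechanism == "reverse_orientation":
        pairs = _find_pairs(retro, "CT", "AC", (lo, hi), margin)
        seq = retro
        if pairs:
            a, b = pairs[int(rng.integers(0, len(pairs)))]
        else:
            a = int(rng.integers(margin, len(retro) - margin - hi))
            b = a + int(rng.integers(lo, hi + 1))
            chars = list(retro)
            for pos, want in ((a, "C"), (a + 1, "T"), (b - 2, "A"), (b - 1, "C")):
                if chars[pos] != want:
                    chars[pos] = want
                    edits.append(pos)
            seq = "".join(chars)
    else:
        raise ValueError(f"unknown mechanism {mechanism!r}")

    protected = set(edits)
    for pos in (a, a + 1, b - 2, b - 1):
        protected.add(pos)
    return {
        "seq": seq,
        "intron": (a, b),
        "protected": protected,
        "edits": edits,
        "comp_indel": comp_indel,
    }


def diverge(seq: str, config: SimulationConfig, rng: np.random.Generator,
            protected: set[int] | None = None,
            indel_exclusion: tuple[int, int] | None = None) -> dict:
    """Apply substitutions and short indels.

    ``protected`` positions are never substituted; indels are kept out of
    ``indel_exclusion`` (the intron plus its frameshift-accounting
    window) and out of the outermost 30 bases.  Returns the diverged
    sequence, the number of substitutions, the applied indels and the
    shift they induce at any downstream coordinate.
    """
    protected = protected or set()
    chars = list(seq)
    n_subs = 0
    for i in np.nonzero(rng.random(len(chars)) < config.sub_rate)[0]:
        i = int(i)
        if i in protected:
            continue
        alt = "ACGT".replace(chars[i].upper(), "")
        chars[i] = alt[int(rng.integers(0, len(alt)))]
        n_subs += 1
    out = "".join(chars)

    n_indels = int(rng.poisson(config.indel_rate * len(out)))
    events = []
    for _ in range(n_indels):
        pos = int(rng.integers(30, max(31, len(out) - 30)))
        if indel_exclusion and indel_exclusion[0] <= pos <= indel_exclusion[1]:
            continue
        kind = "insertion" if rng.random() < 0.5 else "deletion"
        length = int(rng.integers(config.indel_len[0], config.indel_len[1] + 1))
        events.append((pos, kind, length))
    events.sort(reverse=True)
    applied = []
    for pos, kind, length in events:
        if kind == "insertion":
            out = out[:pos] + random_seq(rng, length) + out[pos:]
        else:
            if indel_exclusion and pos < indel_exclusion[0] <= pos + length:
                continue  # would erode the protected window
            out = out[:pos] + out[pos + length:]
        applied.append((pos, kind, length))
    return {"seq": out, "n_subs": n_subs, "indels": applied}


def _shift_from_indels(pos: int, indels) -> int:
    """Coordinate shift at ``pos`` induced by indels applied upstream."""
    shift = 0
    for p, kind, length in indels:
        if p < pos:
            shift += length if kind == "insertion" else -length
    return shift


# ---------------------------------------------------------------------------
# whole-dataset simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    config: SimulationConfig
    seed: int
    genome_records: dict[str, str]
    parents: dict[str, GeneModel]
    retro_annotations: dict[str, GeneModel]
    truth: pd.DataFrame
    proteins: dict[str, str]
    transcripts: list[Bed12Record]
    repeats: list[GenomicInterval]

    @property
    def annotation(self) -> dict[str, GeneModel]:
        return {**self.parents, **self.retro_annotations}


def simulate_dataset(config: SimulationConfig | None = None,
                     seed: int = 0) -> SimulatedDataset:
    """Generate a full fixture: genome, annotation, truth labels.

    Deterministic for a fixed (config, seed)."""
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(seed)

    # --- parents on chr1 ------------------------------------------------
    parents: dict[str, GeneModel] = {}
    parent_info: dict[str, dict] = {}
    proteins: dict[str, str] = {}
    chr1_parts: list[str] = []
    pos = 0
    for i in range(config.n_parents):
        gid = f"parent{i + 1:02d}"
        spacer = random_seq(rng, int(rng.integers(*config.intergenic)))
        chr1_parts.append(spacer)
        pos += len(spacer)
        info = generate_parent_gene(config, rng)
        exons = [GenomicInterval("chr1", pos + s, pos + e)
                 for s, e in info["exons_rel"]]
        tid = f"{gid}.t1"
        gene = GeneModel(gid, "chr1", "+",
                         exons={tid: exons},
                         cds={tid: [GenomicInterval("chr1", iv.start, iv.end)
                                    for iv in exons]},
                         protein=info["protein"])
        parents[gid] = gene
        parent_info[gid] = info
        proteins[gid] = info["protein"]
        chr1_parts.append(info["seq"])
        pos += len(info["seq"])
    chr1_parts.append(random_seq(rng, int(rng.integers(*config.intergenic))))
    chr1 = "".join(chr1_parts)

    # --- retrocopies on chr2 --------------------------------------------
    mech_names = list(MECHANISMS)
    mech_p = [config.mechanism_probs[m] for m in mech_names]
    event_mechs = [mech_names[int(k)] for k in
                   rng.choice(len(mech_names), config.n_gain_events, p=mech_p)]
    parent_ids = list(parents)
    truth_rows: list[TruthRecord] = []
    retro_annotations: dict[str, GeneModel] = {}
    transcripts: list[Bed12Record] = []
    repeats: list[GenomicInterval] = []
    chr2_parts: list[str] = []
    pos = 0

    for i in range(config.n_retrocopies):
        rid = f"retro{i + 1:02d}"
        pid = parent_ids[int(rng.integers(0, len(parent_ids)))]
        mech = event_mechs[i] if i < config.n_gain_events else "none"
        mrna = parent_info[pid]["cds"]
        retro = mrna
        intron = None
        protected: set[int] = set()
        edits: list[int] = []
        comp_indel = None
        if mech != "none":
            inj = inject_intron_gain(retro, mech, config, rng)
            retro = inj["seq"]
            intron = inj["intron"]
            protected = inj["protected"]
            edits = inj["edits"]
            comp_indel = inj["comp_indel"]
        exclusion = (intron[0] - 120, intron[1] + 120) if intron else None
        div = diverge(retro, config, rng, protected, exclusion)
        retro = div["seq"]
        if intron:
            shift_a = _shift_from_indels(intron[0], div["indels"])
            shift_b = _shift_from_indels(intron[1], div["indels"])
            intron = (intron[0] + shift_a, intron[1] + shift_b)
        retro = retropose(retro, config, rng)
        L = len(retro)

        spacer = random_seq(rng, int(rng.integers(*config.retro_spacing)))
        chr2_parts.append(spacer)
        pos += len(spacer)
        strand = "+" if rng.random() < 0.5 else "-"
        genomic = retro if strand == "+" else revcomp(retro)
        off = pos
        chr2_parts.append(genomic)
        pos += L

        annotated_strand = strand
        if mech == "reverse_orientation":
            annotated_strand = "-" if strand == "+" else "+"

        def to_genome(local: int) -> int:
            return off + local if strand == "+" else off + L - local

        g_intron = (-1, -1)
        if intron:
            lo_, hi_ = (to_genome(intron[0]), to_genome(intron[1]))
            g_intron = (min(lo_, hi_), max(lo_, hi_))

        # annotation (skip poly(A) tail)
        tx_lo_local, tx_hi_local = 0, L - config.polya_len
        g_lo = min(to_genome(tx_lo_local), to_genome(tx_hi_local))
        g_hi = max(to_genome(tx_lo_local), to_genome(tx_hi_local))
        tid = f"{rid}.t1"
        if intron:
            exon_ivs = sorted([
                GenomicInterval("chr2", g_lo, g_intron[0]),
                GenomicInterval("chr2", g_intron[1], g_hi),
            ], key=lambda iv: iv.start)
        else:
            exon_ivs = [GenomicInterval("chr2", g_lo, g_hi)]
        coding = mech != "reverse_orientation"
        retro_annotations[rid] = GeneModel(
            rid, "chr2", annotated_strand,
            exons={tid: exon_ivs},
            cds={tid: [GenomicInterval("chr2", iv.start, iv.end)
                       for iv in exon_ivs]} if coding else {},
        )

        indel_repr = ";".join(
            f"{kind}@{p}:{ln}" for p, kind, ln in sorted(div["indels"]))
        if comp_indel:
            kind, p, ln = comp_indel
            indel_repr = (f"{kind}@{p}:{ln}(comp)" +
                          (";" + indel_repr if indel_repr else ""))
        truth_rows.append(TruthRecord(
            retro_id=rid, parent_id=pid, chrom="chr2",
            start=off, end=off + L, strand=strand,
            annotated_strand=annotated_strand, mechanism=mech,
            intron_start=g_intron[0], intron_end=g_intron[1],
            intron_length=(intron[1] - intron[0]) if intron else 0,
            n_substitutions=div["n_subs"], n_edit_bases=len(edits),
            indels=indel_repr,
        ))

        if intron:
            blk1 = (max(0, g_intron[0] - 80), g_intron[0])
            blk2 = (g_intron[1], g_intron[1] + 80)
            transcripts.append(Bed12Record(
                "chr2", blk1[0], blk2[1], f"est_{rid}", 1000,
                annotated_strand,
                [blk1[0], blk2[0]], [blk1[1] - blk1[0], blk2[1] - blk2[0]],
            ))

    # --- DNA-duplication decoys (parent copied with introns) -------------
    for i in range(config.n_decoys):
        pid = parent_ids[int(rng.integers(0, len(parent_ids)))]
        rid = f"decoy{i + 1:02d}"
        spacer = random_seq(rng, int(rng.integers(*config.retro_spacing)))
        chr2_parts.append(spacer)
        pos += len(spacer)
        seq = parent_info[pid]["seq"]
        truth_rows.append(TruthRecord(
            retro_id=rid, parent_id=pid, chrom="chr2",
            start=pos, end=pos + len(seq), strand="+",
            annotated_strand="+", mechanism="none", is_decoy=True,
        ))
        chr2_parts.append(seq)
        pos += len(seq)

    # a few repeat intervals in intergenic space (never over a locus)
    spacer = random_seq(rng, 600)
    chr2_parts.append(spacer)
    repeats.append(GenomicInterval("chr2", pos + 100, pos + 400))
    pos += len(spacer)
    chr2 = "".join(chr2_parts)

    truth = pd.DataFrame([asdict(t) for t in truth_rows])
    return SimulatedDataset(
        config=config, seed=seed,
        genome_records={"chr1": chr1, "chr2": chr2},
        parents=parents, retro_annotations=retro_annotations,
        truth=truth, proteins=proteins,
        transcripts=transcripts, repeats=repeats,
    )


def write_dataset(dataset: SimulatedDataset, out_dir: str) -> dict[str, str]:
    """Emit the fixture as standard files; returns the path map."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "genome": os.path.join(out_dir, "genome.fa"),
        "annotation": os.path.join(out_dir, "annotation.gff3"),
        "truth": os.path.join(out_dir, "truth.tsv"),
        "proteins": os.path.join(out_dir, "proteins.fa"),
        "transcripts": os.path.join(out_dir, "transcripts.bed"),
        "repeats": os.path.join(out_dir, "repeats.bed"),
        "meta": os.path.join(out_dir, "meta.json"),
    }
    write_fasta(dataset.genome_records, paths["genome"])
    write_annotation(dataset.annotation, paths["annotation"])
    dataset.truth.to_csv(paths["truth"], sep="\t", index=False)
    write_fasta(dataset.proteins, paths["proteins"])
    write_bed12(dataset.transcripts, paths["transcripts"])
    with open(paths["repeats"], "w") as fh:
        for iv in dataset.repeats:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
    with open(paths["meta"], "w") as fh:
        json.dump({"seed": dataset.seed, "config": asdict(dataset.config)},
                  fh, indent=2, default=str)
    return paths


# ---------------------------------------------------------------------------
# codon-level divergence (for rate-estimation benchmarks)
# ---------------------------------------------------------------------------

def _inverse_jukes_cantor(d: float) -> float:
    return 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))


def simulate_codon_divergence(n_codons: int, ks: float, omega: float,
                              rng: np.random.Generator) -> tuple[str, str]:
    """A pair of coding sequences diverged at known Ks and Ka/Ks.

    Substitution counts are drawn from the expected proportions of
    synonymous and nonsynonymous changes per NG86 site (Jukes-Cantor
    inverted to per-site proportions), each placed as a single change in
    a distinct codon so the realized divergence matches the target up to
    binomial sampling noise.
    """
    from retrointron.kaks import GENETIC_CODE, SENSE_CODONS, ng86_site_count

    codons = [SENSE_CODONS[i]
              for i in rng.integers(0, len(SENSE_CODONS), n_codons)]
    S = N = 0.0
    for c in codons:
        s, n = ng86_site_count(c)
        S += s
        N += n
    n_syn = int(round(_inverse_jukes_cantor(ks) * S))
    n_non = int(round(_inverse_jukes_cantor(ks * omega) * N))

    derived = list(codons)
    order = rng.permutation(n_codons)
    syn_done = non_done = 0
    for idx in order:
        c = derived[idx]
        if c != codons[idx]:
            continue
        aa = GENETIC_CODE[c]
        muts = []
        for pos in range(3):
            for alt in "ACGT":
                if alt == c[pos]:
                    continue
                m = c[:pos] + alt + c[pos + 1:]
                if GENETIC_CODE[m] == "*":
                    continue
                muts.append((m, GENETIC_CODE[m] == aa))
        rng.shuffle(muts)
        if syn_done < n_syn:
            pick = next((m for m, syn in muts if syn), None)
            if pick:
                derived[idx] = pick
                syn_done += 1
                continue
        if non_done < n_non:
            pick = next((m for m, syn in muts if not syn), None)
            if pick:
                derived[idx] = pick
                non_done += 1
        if syn_done >= n_syn and non_done >= n_non:
            break
    return "".join(codons), "".join(derived)
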