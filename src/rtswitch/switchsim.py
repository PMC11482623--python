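"""Stochastic model of template-switching library preparation.

A molecule's path through library prep is modeled as:

1. a transcript is drawn from the spike-in ladder proportional to its
   concentration and copied end-to-end into cDNA (the processive-enzyme
   assumption: no internal drop-off by default);
2. the RT's terminal-transferase activity appends a nontemplated overhang of
   up to three nucleotides; base identity at each position competes
   proportionally to incorporation rate x dNTP concentration, and chain
   extension is governed by per-step continuation probabilities;
3. the template-switching oligo (TSO) anneals to the overhang; the switch
   succeeds as a Bernoulli event with probability
   base efficiency x pairing score x 5'-modification penalty,
   where the pairing score multiplies per-position pair weights
   (Watson-Crick = strong, G:U wobble = weak, mismatch = 0) and the penalty
   reflects the bulk of the RNA template's 5' end (hydroxyl < triphosphate
   < m7G cap);
4. unblocked TSOs support cycled re-switching, producing geometric
   concatemer counts; a bulky 5' block on the TSO caps the count at one.

All randomness flows from a single counter-based (Philox) stream per call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "TSO",
    "SwitchParams",
    "ReadRecord",
    "sample_nta_overhang",
    "pairing_score",
    "switch_probability",
    "sample_concatemers",
    "simulate_library",
    "cross_hybridization_check",
    "emit_fasta",
    "parse_truth_header",
    "reads_to_dataframe",
    "library_efficiency",
]

_DNA = set("ACGT")
_RNA = set("ACGU")
_MODS = ("hydroxyl", "triphosphate", "m7G")
_BLOCKS = ("none", "abasic_x5", "abasic_x3", "trebler", "trityl")


@dataclass(frozen=True)
class TSO:
    """A template-switching oligonucleotide, written 5'->3'."""

    sequence: str
    chemistry: str = "DNA"
    blocked_5prime: bool = False
    block_name: str = "none"

    def __post_init__(self):
        if self.chemistry not in ("RNA", "DNA"):
            raise ValueError("chemistry must be 'RNA' or 'DNA'")
        if len(self.sequence) < 3:
            raise ValueError("TSO must be at least 3 nt long")
        alphabet = _RNA if self.chemistry == "RNA" else _DNA
        if not set(self.sequence) <= alphabet:
            raise ValueError(
                f"sequence contains characters outside the {self.chemistry} alphabet")
        if self.block_name not in _BLOCKS:
            raise ValueError(f"unknown 5' block {self.block_name!r}")
        if self.blocked_5prime and self.block_name == "none":
            raise ValueError("blocked_5prime requires a named block")
        if not self.blocked_5prime and self.block_name != "none":
            raise ValueError("a named block implies blocked_5prime")

    @property
    def three_prime_trinucleotide(self) -> str:
        return self.sequence[-3:]


class SwitchParams(BaseModel):
    """All simulator knobs, with study-condition defaults.

    Incorporation rates default to the measured first-step NTA rate constants
    (A strongly preferred, G weak, C/T marginal); dNTP concentrations default
    to the biased mix (0.8 mM dATP, 0.4 mM each of the others).  Pair weights
    make Watson-Crick pairs full strength, the G:U wobble weak but nonzero,
    and mismatches inert.  5'-modification penalties are normalized to the
    hydroxyl reference, with triphosphate 20/35 and m7G 10/35 of it, and the
    base switching efficiency defaults to 0.35 (the hydroxyl-template level
    under optimized conditions).
    """

    incorporation_rate: dict[str, float] = Field(
        default={"A": 0.19, "G": 0.035, "C": 0.002, "T": 0.002})
    dntp_conc: dict[str, float] = Field(
        default={"A": 0.8, "G": 0.4, "C": 0.4, "T": 0.4})
    step_continuation: tuple[float, ...] = (0.96, 0.96, 0.86)
    pair_weight: dict[str, float] = Field(
        default={"AT_AU": 1.0, "GC": 1.0, "GU_wobble": 0.15, "mismatch": 0.0})
    mod_penalty: dict[str, float] = Field(
        default={"hydroxyl": 1.0, "triphosphate": 20 / 35, "m7G": 10 / 35})
    base_switch_eff: float = 0.35
    reswitch_prob: float = 0.3
    dropoff_rate: float = 0.0  # per-nt internal termination; 0 = processive

    @field_validator("incorporation_rate", "dntp_conc")
    @classmethod
    def _bases_nonneg(cls, v):
        if set(v) != _DNA:
            raise ValueError("must map exactly the bases A, C, G, T")
        if any(x < 0 for x in v.values()):
            raise ValueError("rates/concentrations must be non-negative")
        return v

    @field_validator("step_continuation")
    @classmethod
    def _steps_valid(cls, v):
        if not 1 <= len(v) <= 3:
            raise ValueError("step_continuation must have length 1-3")
        if any(not 0 <= p <= 1 for p in v):
            raise ValueError("continuation probabilities must be in [0, 1]")
        return v

    @field_validator("pair_weight")
    @classmethod
    def _weights_valid(cls, v):
        required = {"AT_AU", "GC", "GU_wobble", "mismatch"}
        if set(v) != required:
            raise ValueError(f"pair_weight must map exactly {sorted(required)}")
        if any(not 0 <= w <= 1 for w in v.values()):
            raise ValueError("pair weights must be in [0, 1]")
        if not (v["mismatch"] <= v["GU_wobble"] <= min(v["AT_AU"], v["GC"])):
            raise ValueError(
                "require mismatch <= GU_wobble <= min(AT_AU, GC) weights")
        return v

    @field_validator("mod_penalty")
    @classmethod
    def _penalties_valid(cls, v):
        if set(v) != set(_MODS):
            raise ValueError(f"mod_penalty must map exactly {_MODS}")
        if any(not 0 < f <= 1 for f in v.values()):
            raise ValueError("penalty factors must be in (0, 1]")
        return v

    @model_validator(mode="after")
    def _probs_valid(self):
        if not 0 <= self.base_switch_eff <= 1:
            raise ValueError("base_switch_eff must be in [0, 1]")
        if not 0 <= self.reswitch_prob < 1:
            raise ValueError("reswitch_prob must be in [0, 1)")
        if not 0 <= self.dropoff_rate < 1:
            raise ValueError("dropoff_rate must be in [0, 1)")
        return self

    def base_probabilities(self) -> tuple[np.ndarray, tuple[str, ...]]:
        """Per-position incorporation probabilities under rate x conc competition."""
        bases = ("A", "C", "G", "T")
        w = np.array([self.incorporation_rate[b] * self.dntp_conc[b]
                      for b in bases])
        total = w.sum()
        if total <= 0:
            raise ValueError("all effective incorporation rates are zero")
        return w / total, bases


@dataclass
class ReadRecord:
    """One simulated library molecule with its ground truth."""

    transcript_id: str
    cdna_len: int
    overhang: str
    n_tso_copies: int
    template_5mod: str

    def __post_init__(self):
        if self.template_5mod not in _MODS:
            raise ValueError(f"unknown 5' modification {self.template_5mod!r}")
        if not 0 <= len(self.overhang) <= 3:
            raise ValueError("overhang length must be 0-3")
        if self.n_tso_copies < 0:
            raise ValueError("n_tso_copies must be non-negative")


# ---------------------------------------------------------------------------
# elementary sampling operations

def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.Generator(np.random.Philox(int(seed_or_rng)))


def _sample_overhangs(params: SwitchParams, n: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Vectorized overhang sampling: array of strings of length 0-3."""
    probs, bases = params.base_probabilities()
    max_len = len(params.step_continuation)
    # chain length: perform step i given step i-1, prob step_continuation[i]
    lengths = np.zeros(n, dtype=int)
    alive = np.ones(n, dtype=bool)
    for p in params.step_continuation:
        go = rng.random(n) < p
        alive &= go
        lengths += alive
    base_idx = rng.choice(len(bases), size=(n, max_len), p=probs)
    letters = np.array(bases)[base_idx]
    out = np.empty(n, dtype=object)
    for i in range(n):
        out[i] = "".join(letters[i, : lengths[i]])
    return out


def sample_nta_overhang(params: SwitchParams, rng_seed=0) -> str:
    """Draw one nontemplated overhang (up to 3 nt, seeded)."""
    return str(_sample_overhangs(params, 1, _rng(rng_seed))[0])


def _pair_type(overhang_base: str, tso_base: str) -> str:
    a = overhang_base.upper().replace("U", "T")
    b = tso_base.upper().replace("U", "T")
    if {a, b} in ({"A", "T"},):
        return "AT_AU"
    if {a, b} == {"G", "C"}:
        return "GC"
    if {a, b} == {"G", "T"}:
        return "GU_wobble"
    return "mismatch"


def pairing_score(overhang: str, tso_3prime: str,
                  params: SwitchParams | None = None) -> float:
    """Product of per-position pair weights over the overhang:TSO duplex.

    The overhang (written 5'->3' in order of addition) anneals antiparallel
    to the TSO's 3'-terminal nucleotides.  An empty overhang scores 0: with
    nothing to anneal to, switching cannot initiate.
    """
    params = params or SwitchParams()
    if len(overhang) > 3:
        raise ValueError("overhang length must be 0-3")
    valid = _DNA | _RNA
    if not set(overhang.upper()) <= valid or not set(tso_3prime.upper()) <= valid:
        raise ValueError("non-nucleotide characters in overhang or TSO end")
    if not overhang:
        return 0.0
    if len(tso_3prime) < len(overhang):
        raise ValueError("TSO 3' end shorter than the overhang")
    partner = tso_3prime[-len(overhang):][::-1]  # antiparallel register
    score = 1.0
    for ob, tb in zip(overhang, partner):
        score *= params.pair_weight[_pair_type(ob, tb)]
    return float(score)


def switch_probability(overhang: str, tso: TSO, template_5mod: str,
                       params: SwitchParams) -> float:
    """Per-molecule switching probability: base x pairing x 5'-mod penalty."""
    if template_5mod not in _MODS:
        raise ValueError(f"unknown 5' modification {template_5mod!r}")
    p = (params.base_switch_eff
         * pairing_score(overhang, tso.three_prime_trinucleotide, params)
         * params.mod_penalty[template_5mod])
    return float(np.clip(p, 0.0, 1.0))


def sample_concatemers(params: SwitchParams, tso: TSO, rng_seed=0) -> int:
    """Number of tandem TSO copies on a molecule that switched at least once.

    Blocked TSOs cannot be re-initiated on, so the count is always 1;
    otherwise each completed switch re-enters the cycle with probability
    ``reswitch_prob``, giving a geometric count with mean 1/(1 - p).
    """
    if tso.blocked_5prime or params.reswitch_prob == 0.0:
        return 1
    rng = _rng(rng_seed)
    return int(rng.geometric(1.0 - params.reswitch_prob))


# ---------------------------------------------------------------------------
# library simulation

def simulate_library(ladder, params: SwitchParams, tso: TSO,
                     n_molecules: int, seed: int = 0,
                     template_5mod="hydroxyl") -> list[ReadRecord]:
    """Simulate a spike-in library molecule by molecule (vectorized).

    Parameters
    ----------
    ladder : TranscriptLadder
        Spike-in transcripts with lengths and relative concentrations.
    template_5mod : str or sequence of str
        5'-end chemistry of the RNA templates; a scalar applies to every
        molecule, a sequence must have one entry per molecule.

    Records carry the ground-truth transcript identity; identical seeds give
    identical libraries.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be at least 1")
    if len(ladder) == 0:
        raise ValueError("ladder is empty")
    conc = np.asarray(ladder.concentrations, dtype=float)
    total = conc.sum()
    if total <= 0:
        raise ValueError("total ladder concentration must be positive")
    rng = _rng(seed)

    idx = rng.choice(len(ladder), size=n_molecules, p=conc / total)
    lengths = np.asarray(ladder.lengths, dtype=int)[idx]
    if params.dropoff_rate > 0:  # distributive-enzyme option; default off
        survive = rng.geometric(params.dropoff_rate, size=n_molecules)
        lengths = np.minimum(lengths, survive)

    overhangs = _sample_overhangs(params, n_molecules, rng)

    if isinstance(template_5mod, str):
        mods = np.full(n_molecules, template_5mod, dtype=object)
    else:
        mods = np.asarray(template_5mod, dtype=object)
        if mods.size != n_molecules:
            raise ValueError("template_5mod sequence must match n_molecules")

    # switching probability depends only on (overhang, mod): cache per pair
    cache: dict[tuple[str, str], float] = {}
    p_switch = np.empty(n_molecules)
    for i in range(n_molecules):
        key = (overhangs[i], mods[i])
        if key not in cache:
            cache[key] = switch_probability(overhangs[i], tso, mods[i], params)
        p_switch[i] = cache[key]

    switched = rng.random(n_molecules) < p_switch
    copies = np.zeros(n_molecules, dtype=int)
    n_sw = int(switched.sum())
    if n_sw:
        if tso.blocked_5prime or params.reswitch_prob == 0.0:
            copies[switched] = 1
        else:
            copies[switched] = rng.geometric(1.0 - params.reswitch_prob,
                                             size=n_sw)

    ids = np.asarray(ladder.transcript_ids, dtype=object)[idx]
    return [
        ReadRecord(str(ids[i]), int(lengths[i]), str(overhangs[i]),
                   int(copies[i]), str(mods[i]))
        for i in range(n_molecules)
    ]


def library_efficiency(reads: Iterable[ReadRecord]) -> float:
    """Realized switching efficiency: fraction of molecules with >= 1 TSO copy."""
    reads = list(reads)
    if not reads:
        raise ValueError("empty read list")
    return sum(r.n_tso_copies >= 1 for r in reads) / len(reads)


def reads_to_dataframe(reads: Sequence[ReadRecord]):
    import pandas as pd

    return pd.DataFrame(
        {
            "transcript_id": [r.transcript_id for r in reads],
            "cdna_len": [r.cdna_len for r in reads],
            "overhang": [r.overhang for r in reads],
            "n_tso_copies": [r.n_tso_copies for r in reads],
            "template_5mod": [r.template_5mod for r in reads],
        }
    )


# ---------------------------------------------------------------------------
# sequence-level utilities

_COMPLEMENT = {"A": "T", "T": "A", "U": "A", "C": "G", "G": "C"}


def _revcomp_dna(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


def cross_hybridization_check(primer: str, tso: TSO) -> int:
    """Longest contiguous Watson-Crick complementary run between primer and TSO.

    Both sequences are taken 5'->3'; annealing is antiparallel, so the result
    is the longest common substring between the primer and the reverse
    complement of the TSO (U treated as T).  A primer/TSO pair built from
    {C, T} only cannot pair at all and scores 0.
    """
    if not primer or not tso.sequence:
        raise ValueError("primer and TSO must be nonempty")
    p = primer.upper().replace("U", "T")
    if not set(p) <= _DNA:
        raise ValueError("invalid characters in primer")
    q = _revcomp_dna(tso.sequence).replace("U", "T")
    # O(n*m) dynamic program for the longest common substring
    best = 0
    prev = np.zeros(len(q) + 1, dtype=int)
    for a in p:
        cur = np.zeros(len(q) + 1, dtype=int)
        for j, b in enumerate(q, start=1):
            if a == b:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = int(cur[j])
        prev = cur
    return best


def emit_fasta(reads: Sequence[ReadRecord], ladder, tso: TSO,
               primer: str) -> str:
    """Render library molecules as literal cDNA-strand FASTA records.

    Each sequence is primer + reverse-complement(transcript 3' segment) +
    (overhang + reverse-complement(TSO)) per switching cycle.  The header
    encodes the ground truth as ``id|copies|mod`` and round-trips through
    :func:`parse_truth_header`.
    """
    from io import StringIO

    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    seqs = ladder.sequence_map()
    records = []
    tso_rc = _revcomp_dna(tso.sequence)
    for i, r in enumerate(reads):
        if r.transcript_id not in seqs:
            raise KeyError(
                f"transcript {r.transcript_id!r} has no sequence in the ladder")
        template = seqs[r.transcript_id]
        cdna = _revcomp_dna(template[-r.cdna_len:])
        parts = [primer.upper(), cdna]
        for _ in range(r.n_tso_copies):
            parts.append(r.overhang)
            parts.append(tso_rc)
        records.append(
            SeqRecord(Seq("".join(parts)),
                      id=f"{r.transcript_id}|{r.n_tso_copies}|{r.template_5mod}",
                      description=""))
    buf = StringIO()
    SeqIO.write(records, buf, "fasta")
    return buf.getvalue()


def parse_truth_header(header: str) -> tuple[str, int, str]:
    """Recover (transcript_id, n_tso_copies, template_5mod) from a read id."""
    tid, copies, mod = header.split("|")
    return tid, int(copies), mod
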