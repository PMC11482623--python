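"""Synthetic-data generators for every pipeline input.

These stand in for the raw experimental artifacts: kinetic band-fraction
time courses, gel lane traces, and spike-in transcript ladders.  The default
ladder mirrors the standard external-control design: 92 transcripts of
250-2000 nt whose concentrations span exactly six orders of magnitude, plus
a 69-isoform set grouped into 7 loci with lengths of 200-2500 nt.  Every
generator is a pure function of its configuration (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .gelquant import BAND_LABELS, LaneProfile
from .kinetics import KineticModel, TimeCourse, simulate_timecourse
from .quantify import TranscriptLadder

__all__ = [
    "GeneratorConfig",
    "BAND_CENTERS",
    "default_band_windows",
    "make_ercc_like_ladder",
    "make_sirv_like_set",
    "make_timecourse_fixture",
    "make_gel_fixture",
    "ladder_to_fasta",
]

#: fixed migration coordinate of each band's peak center (arbitrary units)
BAND_CENTERS = {
    "primer": 10.0,
    "nta_1": 16.0,
    "nta_2": 22.0,
    "nta_3": 28.0,
    "ts_1": 45.0,
    "ts_2": 60.0,
    "ts_3plus": 75.0,
}


class GeneratorConfig(BaseModel):
    """Configuration of the synthetic-data generators (all seeded)."""

    seed: int = 0
    # spike-in ladder
    n_ercc_like: int = 92
    length_range: tuple[int, int] = (250, 2000)
    n_logs: int = 6
    n_sirv_like: int = 69
    n_sirv_loci: int = 7
    sirv_length_range: tuple[int, int] = (200, 2500)
    # gel rendering
    gel_peak_width: float = 0.8
    gel_baseline: float = 0.0
    gel_grid_step: float = 0.05

    @model_validator(mode="after")
    def _check(self):
        if self.n_logs < 1:
            raise ValueError("n_logs must be >= 1")
        for lo, hi in (self.length_range, self.sirv_length_range):
            if lo <= 0 or hi < lo:
                raise ValueError("length ranges must be positive and ordered")
        if self.gel_peak_width <= 0 or self.gel_grid_step <= 0:
            raise ValueError("gel peak width and grid step must be positive")
        return self


def _random_sequences(rng: np.random.Generator, lengths) -> list:
    bases = np.array(list("ACGT"))
    return ["".join(bases[rng.integers(0, 4, size=int(n))]) for n in lengths]


def make_ercc_like_ladder(cfg: GeneratorConfig | None = None,
                          with_sequences: bool = False) -> TranscriptLadder:
    """External-control-style ladder: geometric concentration grid.

    Concentrations are placed on a geometric grid spanning exactly
    ``n_logs`` decades (equally many transcripts per decade), so
    max/min = 10**n_logs by construction.  Lengths are uniform over the
    configured range.
    """
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_ercc_like
    ids = [f"SYN-ERCC-{i + 1:04d}" for i in range(n)]
    lengths = rng.integers(cfg.length_range[0], cfg.length_range[1] + 1, size=n)
    if n == 1:
        conc = np.ones(1)
    else:
        conc = 10.0 ** (cfg.n_logs * np.arange(n) / (n - 1))
    seqs = _random_sequences(rng, lengths) if with_sequences else None
    return TranscriptLadder(ids, lengths, conc, ["ercc_like"] * n, sequences=seqs)


def make_sirv_like_set(cfg: GeneratorConfig | None = None,
                       with_sequences: bool = False) -> TranscriptLadder:
    """Isoform-style set: transcripts partitioned into gene loci.

    The default 69 transcripts are split as evenly as possible over 7 loci;
    per-locus relative concentrations cycle over a short grid so the set has
    more than one abundance level.
    """
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed + 1)
    n, n_loci = cfg.n_sirv_like, cfg.n_sirv_loci
    base, extra = divmod(n, n_loci)
    locus_sizes = [base + (1 if i < extra else 0) for i in range(n_loci)]
    ids, groups, conc = [], [], []
    conc_grid = (0.5, 1.0, 2.0, 4.0)
    for li, size in enumerate(locus_sizes):
        for j in range(size):
            ids.append(f"SYN-SIRV{li + 1}{chr(97 + j)}")
            groups.append(f"sirv_like_locus{li + 1}")
            conc.append(conc_grid[(li + j) % len(conc_grid)])
    lengths = rng.integers(cfg.sirv_length_range[0],
                           cfg.sirv_length_range[1] + 1, size=n)
    seqs = _random_sequences(rng, lengths) if with_sequences else None
    return TranscriptLadder(ids, lengths, np.array(conc), groups, sequences=seqs)


def make_timecourse_fixture(model: KineticModel, times, noise_sd: float = 0.0,
                            cfg: GeneratorConfig | None = None,
                            label: str = "") -> TimeCourse:
    """Band-fraction time course drawn from the kinetic forward model."""
    cfg = cfg or GeneratorConfig()
    return simulate_timecourse(model, times, noise_sd=noise_sd,
                               seed=cfg.seed, label=label)


def make_gel_fixture(band_fractions: dict,
                     cfg: GeneratorConfig | None = None,
                     lane_id: str = "") -> LaneProfile:
    """Render band fractions as a lane trace of Gaussian peaks.

    Each band becomes a Gaussian of area equal to its fraction, centered at
    the fixed per-label migration coordinate, on a flat baseline.
    """
    cfg = cfg or GeneratorConfig()
    unknown = set(band_fractions) - set(BAND_CENTERS)
    if unknown:
        raise ValueError(f"unknown band labels: {sorted(unknown)}")
    positions = np.arange(0.0, 90.0 + cfg.gel_grid_step, cfg.gel_grid_step)
    trace = np.full_like(positions, cfg.gel_baseline)
    sd = cfg.gel_peak_width
    for label, area in band_fractions.items():
        if area < 0:
            raise ValueError("band fractions must be non-negative")
        mu = BAND_CENTERS[label]
        trace += area * np.exp(-0.5 * ((positions - mu) / sd) ** 2) / (
            sd * np.sqrt(2 * np.pi))
    return LaneProfile(positions, trace, lane_id=lane_id)


def default_band_windows(half_width: float = 2.9) -> dict:
    """Integration windows around the fixed band centers (non-overlapping)."""
    return {label: (mu - half_width, mu + half_width)
            for label, mu in BAND_CENTERS.items()}


def ladder_to_fasta(ladder: TranscriptLadder, path) -> None:
    """Write ladder transcript sequences to FASTA (requires sequences)."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    if ladder.sequences is None:
        raise ValueError("ladder has no sequences; generate with with_sequences=True")
    records = [
        SeqRecord(Seq(s), id=tid, description="")
        for tid, s in zip(ladder.transcript_ids, ladder.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")
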