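"""File formats and pipeline configuration.

CSV is comma-separated UTF-8 with a mandatory header row; the transcript
ladder uses TSV (matching common spike-in sheet style).  Any positional
coordinates in outputs are 0-based half-open.  FASTA goes through Biopython
with headers preserved verbatim and 80-column wrapping on write.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field

from .switchsim import SwitchParams

__all__ = [
    "read_fasta",
    "write_fasta",
    "TSOConfig",
    "LadderConfig",
    "KineticsConfig",
    "FitConfig",
    "SimulateConfig",
    "QuantifyConfig",
    "PipelineConfig",
    "config_hash",
]


def read_fasta(path) -> list:
    """Read FASTA records as (header, sequence) pairs, headers verbatim."""
    from Bio import SeqIO

    out = []
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            header = rec.description if rec.description else rec.id
            out.append((header, str(rec.seq)))
    return out


def write_fasta(records, path) -> None:
    """Write (header, sequence) pairs wrapped at 80 columns."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    seqrecs = [
        SeqRecord(Seq(seq), id=header.split()[0] if header else "",
                  description=header[len(header.split()[0]):].strip()
                  if header else "")
        for header, seq in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=80)
        writer.write_file(seqrecs)


# ---------------------------------------------------------------------------
# pipeline configuration (unknown keys rejected everywhere)

_strict = ConfigDict(extra="forbid")


class TSOConfig(BaseModel):
    model_config = _strict
    sequence: str = "CTCCTCTTCCTCCTCTTT"
    chemistry: str = "DNA"
    blocked_5prime: bool = True
    block_name: str = "abasic_x5"

    def build(self):
        from .switchsim import TSO

        return TSO(self.sequence, self.chemistry, self.blocked_5prime,
                   self.block_name)


class LadderConfig(BaseModel):
    model_config = _strict
    kind: str = "ercc_like"  # or sirv_like
    n_ercc_like: int = 92
    length_range: tuple[int, int] = (250, 2000)
    n_logs: int = 6
    n_sirv_like: int = 69
    n_sirv_loci: int = 7
    sirv_length_range: tuple[int, int] = (200, 2500)
    with_sequences: bool = False


class KineticsConfig(BaseModel):
    model_config = _strict
    k: list[float] = [0.19, 0.61, 0.20]
    a: list[float] = [0.96, 0.96, 0.86]
    times: list[float] = Field(
        default_factory=lambda: [float(t) for t in
                                 (0, 1, 2, 4, 8, 15, 25, 40, 60, 80, 100, 120)])
    noise_sd: float = 0.0


class FitConfig(BaseModel):
    model_config = _strict
    n_steps: int = 3
    n_boot: int = 0  # 0 = no bootstrap


class SimulateConfig(BaseModel):
    model_config = _strict
    n_molecules: int = 10000
    template_5mod: str = "hydroxyl"
    primer: str = "TTTTTTTTTTTTTTTTTT"
    params: SwitchParams = Field(default_factory=SwitchParams)
    tso: TSOConfig = Field(default_factory=TSOConfig)
    write_fasta: bool = False


class QuantifyConfig(BaseModel):
    model_config = _strict
    detection_metric: str = "tpm"
    detection_threshold: float = 0.0


class PipelineConfig(BaseModel):
    """Global seed plus one block per pipeline stage; unknown keys rejected."""

    model_config = _strict
    seed: int = 0
    outdir: str = "rtswitch_run"
    log_level: str = "INFO"
    ladder: LadderConfig = Field(default_factory=LadderConfig)
    kinetics: KineticsConfig = Field(default_factory=KineticsConfig)
    fit: FitConfig = Field(default_factory=FitConfig)
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    quantify: QuantifyConfig = Field(default_factory=QuantifyConfig)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))


def config_hash(config: BaseModel) -> str:
    """Stable sha256 of the canonical JSON form of a config."""
    canon = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()
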