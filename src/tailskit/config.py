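"""Run configuration: one YAML home for every stage's parameters."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path
from typing import Any

import yaml

from tailskit.enrich import PermTestParams
from tailskit.nterm import DigestParams
from tailskit.quant import ChannelDesign, ImputeParams
from tailskit.simulate import SimConfig
from tailskit.substrates import PairingParams

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """All pipeline parameters plus input/output paths.

    Every module's parameters have exactly one home here; the global seed
    seeds every stage that draws random numbers unless a stage seed is set
    explicitly in the YAML.
    """

    proteome_fasta: str | None = None
    signal_peptides_tsv: str | None = None
    peptide_quant_tsv: str | None = None
    lfq_tsv: str | None = None
    timecourse_tsv: str | None = None
    output_dir: str = "tailskit_out"
    log_level: str = "INFO"
    seed: int = 0
    max_cycles: int = 15
    restrict_observed: bool = False
    design: ChannelDesign = field(default_factory=ChannelDesign.default_6plex)
    digest: DigestParams = field(default_factory=DigestParams)
    impute: ImputeParams = field(default_factory=ImputeParams)
    pairing: PairingParams = field(default_factory=PairingParams)
    perm_test: PermTestParams = field(default_factory=PermTestParams)
    sim: SimConfig = field(default_factory=SimConfig)

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["design"] = {c: list(v) for c, v in self.design.channels.items()}
        d["digest"]["cleave_after"] = sorted(self.digest.cleave_after)
        d["pairing"]["allowed_offsets"] = sorted(self.pairing.allowed_offsets)
        d["sim"]["p1_weights"] = dict(self.sim.p1_weights)
        d["sim"]["conversion"] = dict(self.sim.conversion)
        return d


def _build(cls, raw: dict[str, Any], seed: int | None):
    kwargs = dict(raw)
    if seed is not None and "seed" in {f.name for f in fields(cls)}:
        kwargs.setdefault("seed", seed)
    if cls is DigestParams and "cleave_after" in kwargs:
        kwargs["cleave_after"] = frozenset(kwargs["cleave_after"])
    if cls is PairingParams and "allowed_offsets" in kwargs:
        kwargs["allowed_offsets"] = frozenset(kwargs["allowed_offsets"])
    return cls(**kwargs)


def load_config(path: str | Path | None = None,
                overrides: dict[str, Any] | None = None) -> RunConfig:
    """Load a RunConfig from YAML, applying flat top-level overrides."""
    raw: dict[str, Any] = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValueError(f"{path}: config must be a mapping")
            raw = loaded
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})

    seed = int(raw.get("seed", 0))
    design_raw = raw.get("design")
    design = (ChannelDesign({c: (g, int(r)) for c, (g, r) in design_raw.items()})
              if design_raw else ChannelDesign.default_6plex())
    cfg = RunConfig(
        proteome_fasta=raw.get("proteome_fasta"),
        signal_peptides_tsv=raw.get("signal_peptides_tsv"),
        peptide_quant_tsv=raw.get("peptide_quant_tsv"),
        lfq_tsv=raw.get("lfq_tsv"),
        timecourse_tsv=raw.get("timecourse_tsv"),
        output_dir=str(raw.get("output_dir", "tailskit_out")),
        log_level=str(raw.get("log_level", "INFO")),
        seed=seed,
        max_cycles=int(raw.get("max_cycles", 15)),
        restrict_observed=bool(raw.get("restrict_observed", False)),
        design=design,
        digest=_build(DigestParams, raw.get("digest", {}), None),
        impute=_build(ImputeParams, raw.get("impute", {}), seed),
        pairing=_build(PairingParams, raw.get("pairing", {}), None),
        perm_test=_build(PermTestParams, raw.get("perm_test", {}), seed),
        sim=_build(SimConfig, raw.get("sim", {}), seed),
    )
    return cfg
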