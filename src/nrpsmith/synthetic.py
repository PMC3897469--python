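"""Synthetic NRPS domains and assemblies with ground-truth labels.

The generator emulates the geometry of real condensation-superfamily
domains — a ~300-residue Up-Seq core carrying the HHxxxDG active-site
motif, followed by a Down-Seq spacer of 155-175 residues carrying the
subtype's ordered WL signature windows over an i.i.d. background — so
that every pipeline stage (delimitation, motif finding, signature
scanning, classification, isomery inference) can be tested end to end
with known answers.  A/T/Te placeholder segments are plain background
with recorded coordinates; only C/E-domain content is under test.

Everything is driven by a seeded :class:`numpy.random.Generator`: the
same seed reproduces byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .archmodel import DomainAnnotation, DomainToken, IsomeryState
from .downseq import find_active_site
from .logos import (
    AA_ALPHABET,
    PFM,
    WINDOWS_PER_SUBTYPE,
    SignatureModel,
    uniform_background,
)


class GeneratorError(ValueError):
    """Raised for plans or configs the generator cannot satisfy."""


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic generator (defaults mirror real geometry)."""

    seed: int = 0
    background: np.ndarray = field(default_factory=uniform_background)
    upseq_len: int = 300
    spacer_range: tuple[int, int] = (155, 175)  # inclusive uniform
    signal_strength: float = 0.9
    window_len: int = 12
    a_len: int = 500  # A-domain placeholder length
    t_len: int = 80  # T-domain placeholder length
    te_len: int = 250  # Te-domain placeholder length

    def __post_init__(self) -> None:
        if not (0.0 < self.signal_strength <= 1.0):
            raise GeneratorError("signal_strength must be in (0, 1]")


def _random_sequence(rng: np.random.Generator, length: int, bg: np.ndarray) -> list[str]:
    idx = rng.choice(20, size=length, p=bg)
    return [AA_ALPHABET[i] for i in idx]


def example_models(
    window_len: int = 12,
    consensus_weight: float = 0.9,
    seed: int = 7,
) -> dict[DomainToken, SignatureModel]:
    """Deterministic per-subtype signature models for simulation and tests.

    Each subtype gets its spec'd number of WL windows with an independent
    random consensus; within a window column the consensus residue carries
    ``consensus_weight`` and the remaining mass is spread uniformly.  The
    models are a bundled example trained on nothing — they define the
    synthetic study conditions, they are not signatures of real domains.
    """
    rng = np.random.default_rng(seed)
    models: dict[DomainToken, SignatureModel] = {}
    off_weight = (1.0 - consensus_weight) / 19.0
    for subtype in (
        DomainToken.CSTARTER,
        DomainToken.LCL,
        DomainToken.DCL,
        DomainToken.CE,
        DomainToken.E,
        DomainToken.CT,
    ):
        windows = []
        for w in range(WINDOWS_PER_SUBTYPE[subtype]):
            consensus = rng.integers(0, 20, size=window_len)
            freqs = np.full((window_len, 20), off_weight)
            freqs[np.arange(window_len), consensus] = consensus_weight
            windows.append((f"WL{w + 1}", PFM(freqs, np.full(window_len, 30.0))))
        models[subtype] = SignatureModel(subtype, windows)
    return models


def sample_downseq(
    model: SignatureModel,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[str, list[int]]:
    """Draw one Down-Seq with the model's windows planted in order.

    Background residues are i.i.d. from ``config.background``; inside each
    window the consensus residue is emitted with probability
    ``signal_strength``, otherwise a background draw.  Returns the sequence
    and the planted window offsets (relative to the Down-Seq start).
    """
    lo, hi = config.spacer_range
    spacer = int(rng.integers(lo, hi + 1))
    lengths = [pfm.length for pfm in model.window_pfms]
    free = spacer - sum(lengths)
    if free < 0:
        raise GeneratorError(
            f"windows (total {sum(lengths)}) cannot fit in spacer {spacer}"
        )
    k = len(lengths)
    picks = np.sort(rng.choice(free + k, size=k, replace=False))
    offsets = []
    consumed = 0
    for i in range(k):
        offsets.append(int(picks[i]) - i + consumed)
        consumed += lengths[i]
    seq = _random_sequence(rng, spacer, config.background)
    for off, pfm in zip(offsets, model.window_pfms):
        consensus = pfm.consensus()
        for j in range(pfm.length):
            if rng.random() < config.signal_strength:
                seq[off + j] = consensus[j]
            # else: keep the background draw already in place
    return "".join(seq), offsets


@dataclass
class DomainTruth:
    """Everything the generator knows about one emitted C/E domain."""

    subtype: DomainToken | None  # None = background-only Down-Seq
    active_site_offset: int
    window_offsets: list[int]  # relative to Down-Seq start
    upseq_len: int
    spacer_len: int


def synth_domain(
    subtype: DomainToken | None,
    config: GeneratorConfig,
    rng: np.random.Generator,
    models: dict[DomainToken, SignatureModel] | None = None,
) -> tuple[str, DomainTruth]:
    """One full C/E domain: motif-bearing Up-Seq plus signature Down-Seq.

    ``subtype=None`` emits a pure-background Down-Seq (an "unknown" domain
    that should classify as UNKNOWN).  The HHxxxDG motif is planted at a
    recorded offset; the Up-Seq is resampled in the rare case a spurious
    earlier motif match arises, so the recorded offset is always the one
    the motif finder recovers.
    """
    if models is None:
        models = example_models(window_len=config.window_len)
    if subtype is not None and subtype not in models:
        raise GeneratorError(f"no signature model for subtype {subtype}")

    for _ in range(100):
        upseq = _random_sequence(rng, config.upseq_len, config.background)
        motif_off = int(rng.integers(20, config.upseq_len - 27))
        motif = list("HH") + _random_sequence(rng, 3, config.background) + list("DG")
        upseq[motif_off : motif_off + 7] = motif
        found = find_active_site("".join(upseq))
        if found is not None and found[0] == motif_off:
            break
    else:  # pragma: no cover - p(failure) is astronomically small
        raise GeneratorError("could not plant a unique active-site motif")

    if subtype is None:
        lo, hi = config.spacer_range
        spacer = int(rng.integers(lo, hi + 1))
        down = "".join(_random_sequence(rng, spacer, config.background))
        offsets: list[int] = []
    else:
        down, offsets = sample_downseq(models[subtype], config, rng)
    seq = "".join(upseq) + down
    return seq, DomainTruth(subtype, motif_off, offsets, config.upseq_len, len(down))


@dataclass
class ModuleSpec:
    """One planned module: its leading C-subtype (or None) and an E flag."""

    leading: DomainToken | None = DomainToken.LCL
    has_E: bool = False


@dataclass
class GroundTruth:
    """Generator-side answers for a whole synthetic assembly."""

    subtypes: list[tuple[str, tuple[int, int], DomainToken]]  # per C/E core hit
    isomery: list[IsomeryState]  # per module, from the plan by rules R1/R2
    domains: list[DomainTruth]
    flags: list[str] = field(default_factory=list)


@dataclass
class SyntheticAssembly:
    sequences: dict[str, str]
    annotations: list[DomainAnnotation]
    truth: GroundTruth


def truth_isomery(plan: list[list[ModuleSpec]]) -> list[IsomeryState]:
    """Ground-truth D/L states implied by a plan (rules R1 and R2)."""
    flat = [m for protein in plan for m in protein]
    iso = [IsomeryState.L] * len(flat)
    for i, spec in enumerate(flat):
        if spec.has_E:
            iso[i] = IsomeryState.D
        if spec.leading is DomainToken.CE and i > 0:
            iso[i - 1] = IsomeryState.D
    return iso


def synth_assembly(
    module_plan: list[list[ModuleSpec]] | list[ModuleSpec],
    config: GeneratorConfig | None = None,
    models: dict[DomainToken, SignatureModel] | None = None,
    terminal_te: int = 1,
) -> SyntheticAssembly:
    """Emit FASTA-ready protein sequences, a domain table, and ground truth.

    ``module_plan`` is a list of proteins, each a list of
    :class:`ModuleSpec` (a flat list is treated as a single protein).
    Every C/E-superfamily domain (leading C and any E) is emitted as a
    generic ``C?`` core annotation spanning its Up-Seq only, exactly as a
    domain scanner reports the shared superfamily core — recovering the
    subtypes is the classifier's job.  A dual C/E planned on module 1 is
    legal but flagged, mirroring the runtime warning.
    """
    if config is None:
        config = GeneratorConfig()
    if module_plan and isinstance(module_plan[0], ModuleSpec):
        module_plan = [module_plan]  # type: ignore[list-item]
    plan: list[list[ModuleSpec]] = [list(p) for p in module_plan]  # type: ignore[union-attr]
    if not plan or not any(plan):
        raise GeneratorError("empty module plan")
    if models is None:
        models = example_models(window_len=config.window_len)
    rng = np.random.default_rng(config.seed)

    sequences: dict[str, str] = {}
    annotations: list[DomainAnnotation] = []
    truth = GroundTruth([], truth_isomery(plan), [])
    if plan[0][0].leading is DomainToken.CE:
        truth.flags.append("CE_ON_MODULE_1")

    module_index = 0
    for p, protein in enumerate(plan, start=1):
        pid = f"synP{p}"
        parts: list[str] = []
        pos = 0

        def emit_domain(subtype: DomainToken | None) -> None:
            # a C? core hit spanning the Up-Seq, as a domain scanner reports it;
            # subtype None plants a background-only Down-Seq (truth = C_UNK)
            nonlocal pos
            seq, dt = synth_domain(subtype, config, rng, models)
            core = (pos, pos + config.upseq_len)
            annotations.append(
                DomainAnnotation(pid, DomainToken.C_UNK, *core, source="synthetic")
            )
            truth.subtypes.append(
                (pid, core, subtype if subtype is not None else DomainToken.C_UNK)
            )
            truth.domains.append(dt)
            parts.append(seq)
            pos += len(seq)

        def emit_placeholder(kind: DomainToken, length: int) -> None:
            nonlocal pos
            annotations.append(
                DomainAnnotation(pid, kind, pos, pos + length, source="synthetic")
            )
            parts.append("".join(_random_sequence(rng, length, config.background)))
            pos += length

        for spec in protein:
            module_index += 1
            if spec.leading is not None:
                emit_domain(None if spec.leading is DomainToken.C_UNK else spec.leading)
            emit_placeholder(DomainToken.A, config.a_len)
            emit_placeholder(DomainToken.T, config.t_len)
            if spec.has_E:
                emit_domain(DomainToken.E)
        if p == len(plan):
            for _ in range(terminal_te):
                emit_placeholder(DomainToken.TE, config.te_len)
        sequences[pid] = "".join(parts)
    return SyntheticAssembly(sequences, annotations, truth)
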