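"""Data model and parsers for NRPS domain architectures.

A nonribosomal peptide synthetase (NRPS) is an assembly line of *modules*,
each incorporating one monomer into the growing peptide.  The canonical
module layout is ``{(C)-A-T}``: an optional condensation (C) domain, an
adenylation (A) domain selecting the monomer, and a thiolation (T) carrier
domain, with optional tailoring domains (epimerization E, cyclization Cy)
and a terminal thioesterase (Te) releasing the product.  Condensation
domains come in functional subtypes (C-starter, LCL, DCL, dual C/E, fungal
Ct) that this package distinguishes because they carry the information
needed to infer each monomer's D/L isomery.

This module defines the domain-token vocabulary, the architecture-string
dialect (e.g. ``"C/E-A-T-LCL-A-T-Te-Te"``), segmentation of token lists
into modules, assembly-level concatenation across synthetase proteins in
gene order, and the Norine-style monomer string notation.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field


class ArchitectureError(ValueError):
    """Raised for malformed architecture strings or inconsistent token lists."""


class DomainToken(enum.Enum):
    """Catalytic domain vocabulary, including condensation subtypes."""

    CSTARTER = "Cstarter"
    LCL = "LCL"
    DCL = "DCL"
    CE = "C/E"
    CT = "Ct"
    C_UNK = "C?"
    E = "E"
    EBETA = "Eb"
    A = "A"
    T = "T"
    TE = "Te"
    CY = "Cy"
    PKS = "PKS"
    X = "X"

    def __str__(self) -> str:  # canonical rendering
        return self.value


#: Members of the condensation-domain superfamily that can lead a module.
C_TYPES = frozenset(
    {
        DomainToken.CSTARTER,
        DomainToken.LCL,
        DomainToken.DCL,
        DomainToken.CE,
        DomainToken.CT,
        DomainToken.C_UNK,
    }
)

#: Subtypes assignable by classification (EBETA only via explicit annotation).
CLASSIFIABLE_SUBTYPES = (
    DomainToken.CSTARTER,
    DomainToken.LCL,
    DomainToken.DCL,
    DomainToken.CE,
    DomainToken.CT,
    DomainToken.E,
)

_ALIASES = {
    "cstarter": DomainToken.CSTARTER,
    "c-starter": DomainToken.CSTARTER,
    "lcl": DomainToken.LCL,
    "dcl": DomainToken.DCL,
    "c/e": DomainToken.CE,
    "ce": DomainToken.CE,
    "ct": DomainToken.CT,
    "c?": DomainToken.C_UNK,
    "c": DomainToken.C_UNK,
    "cunk": DomainToken.C_UNK,
    "e": DomainToken.E,
    "eb": DomainToken.EBETA,
    "ebeta": DomainToken.EBETA,
    "a": DomainToken.A,
    "t": DomainToken.T,
    "te": DomainToken.TE,
    "cy": DomainToken.CY,
    "pks": DomainToken.PKS,
    "x": DomainToken.X,
}

_MARKUP = re.compile(r"[\^_\s]")


def normalize_token(text: str) -> DomainToken:
    """Normalize one architecture field to a :class:`DomainToken`.

    Markup characters ``^`` and ``_`` (used in superscript/subscript
    notation like ``^L^C_L_``) and case are ignored before alias matching.
    Normalization is idempotent: canonical renderings map back to the same
    member.
    """
    if isinstance(text, DomainToken):
        return text
    key = _MARKUP.sub("", text).lower()
    try:
        return _ALIASES[key]
    except KeyError:
        raise ArchitectureError(f"unrecognized domain token {text!r}") from None


def parse_architecture(text: str) -> list[DomainToken]:
    """Parse a hyphen-separated architecture string into domain tokens.

    Unknown fields raise :class:`ArchitectureError` naming the offending
    field and its 1-based position; they are never silently mapped to X.
    """
    if not text or not text.strip():
        raise ArchitectureError("empty architecture string")
    tokens = []
    for i, fld in enumerate(text.strip().split("-"), start=1):
        try:
            tokens.append(normalize_token(fld))
        except ArchitectureError:
            raise ArchitectureError(
                f"unrecognized domain token {fld!r} at field {i} of {text!r}"
            ) from None
    return tokens


def render_architecture(tokens: list[DomainToken]) -> str:
    """Canonical text form; ``parse_architecture(render_architecture(t)) == t``."""
    return "-".join(str(t) for t in tokens)


@dataclass
class DomainAnnotation:
    """A located catalytic domain on one synthetase protein.

    Coordinates are 0-based half-open internally; on-disk domain tables use
    1-based inclusive coordinates (converted by :mod:`nrpsmith.io`).
    """

    protein_id: str
    kind: DomainToken
    start: int
    end: int
    source: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ArchitectureError(
                f"invalid interval [{self.start}, {self.end}) for "
                f"{self.kind} on {self.protein_id}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Module:
    """One NRPS module: exactly one A domain plus its companions."""

    index: int  # 1-based, assembly-global
    tokens: list[DomainToken]
    protein_id: str = ""
    flags: list[str] = field(default_factory=list)

    @property
    def leading_c(self) -> DomainToken | None:
        return self.tokens[0] if self.tokens and self.tokens[0] in C_TYPES else None

    @property
    def has_E(self) -> bool:
        return DomainToken.E in self.tokens

    @property
    def has_A(self) -> bool:
        return DomainToken.A in self.tokens


def segment_modules(
    tokens: list[DomainToken], protein_id: str = ""
) -> tuple[list[DomainToken], list[Module]]:
    """Segment an ordered token list into a prologue and modules.

    Scanning left to right: a C-superfamily token closes any open module
    and opens a new one; an A token opens a module when none is open (or
    the open one already holds an A); T/E/Te/Cy/PKS/X attach to the open
    module; tokens before the first module form the prologue.  A trailing
    C-type token with no following A (the fungal terminal Ct) attaches to
    the last module as a release domain.  Two C-type tokens with no
    intervening A stay in one module, flagged ``TANDEM_C`` for later
    context rules.  The module count always equals the A-token count.
    """
    prologue: list[DomainToken] = []
    modules: list[Module] = []
    open_tokens: list[DomainToken] | None = None
    open_flags: list[str] = []

    def close() -> None:
        nonlocal open_tokens, open_flags
        if open_tokens is not None:
            modules.append(
                Module(len(modules) + 1, open_tokens, protein_id, open_flags)
            )
            open_tokens = None
            open_flags = []

    for tok in tokens:
        if tok in C_TYPES:
            if open_tokens is not None and DomainToken.A not in open_tokens:
                open_tokens.append(tok)
                if "TANDEM_C" not in open_flags:
                    open_flags.append("TANDEM_C")
            else:
                close()
                open_tokens = [tok]
        elif tok is DomainToken.A:
            if open_tokens is None or DomainToken.A in open_tokens:
                close()
                open_tokens = [tok]
            else:
                open_tokens.append(tok)
        elif tok is DomainToken.E:
            if open_tokens is None:
                raise ArchitectureError(
                    f"E domain with no open module in {render_architecture(tokens)!r}"
                )
            open_tokens.append(tok)
        else:  # T, TE, CY, PKS, X, EBETA
            if open_tokens is None:
                prologue.append(tok)
            else:
                open_tokens.append(tok)
    close()

    # trailing module without an A: fungal terminal Ct (or stray C) becomes
    # a release domain of the previous module
    if modules and not modules[-1].has_A:
        trailing = modules.pop()
        if not modules:
            raise ArchitectureError(
                "architecture contains a C-type domain but no A domain"
            )
        modules[-1].tokens.extend(trailing.tokens)
        modules[-1].flags.append(
            "RELEASE_CT" if trailing.tokens[0] is DomainToken.CT else "TRAILING_C"
        )
        modules[-1].flags.extend(trailing.flags)

    return prologue, modules


class Organism(enum.Enum):
    """Coarse taxonomic hint steering genus-specific prediction rules."""

    PSEUDOMONAS = "pseudomonas"
    BACILLUS = "bacillus"
    FUNGUS = "fungus"
    OTHER = "other"
    UNKNOWN = "unknown"


@dataclass
class Assembly:
    """An NRPS assembly line: ordered synthetases and their global modules."""

    synthetases: list[tuple[str, list[DomainToken]]]
    modules: list[Module]
    prologue: list[tuple[str, list[DomainToken]]]
    organism_hint: Organism = Organism.UNKNOWN

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    @property
    def all_tokens(self) -> list[DomainToken]:
        out: list[DomainToken] = []
        for _, toks in self.prologue:
            out.extend(toks)
        for mod in self.modules:
            out.extend(mod.tokens)
        return out


def concat_assembly(
    synthetases: list[tuple[str, list[DomainToken]]],
    organism_hint: Organism = Organism.UNKNOWN,
) -> Assembly:
    """Concatenate tokenized synthetases in gene order into one assembly.

    Modules are renumbered 1..n across proteins; per-protein prologues are
    kept with their protein attribution.
    """
    if not synthetases:
        raise ArchitectureError("assembly requires at least one synthetase")
    modules: list[Module] = []
    prologue: list[tuple[str, list[DomainToken]]] = []
    for protein_id, tokens in synthetases:
        pro, mods = segment_modules(tokens, protein_id)
        if pro:
            prologue.append((protein_id, pro))
        for mod in mods:
            mod.index = len(modules) + 1
            modules.append(mod)
    return Assembly(list(synthetases), modules, prologue, organism_hint)


class IsomeryState(enum.Enum):
    L = "L"
    D = "D"
    D_UNCONFIRMED = "D?"
    UNKNOWN = "?"


class Topology(enum.Enum):
    LINEAR = "linear"
    CYCLIC = "cyclic"
    PARTIAL_CYCLIC = "partial cyclic"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class Monomer:
    name: str
    isomery: IsomeryState = IsomeryState.L


@dataclass
class MonomerString:
    """A peptide in Norine-style monomeric notation.

    Comma-separated monomer names, ``D-`` prefix for D-isomers, square
    brackets around the whole list for a cyclic peptide, e.g.
    ``[Val,Orn,Leu,D-Phe,Pro,D-Tyr]``.
    """

    monomers: list[Monomer]
    topology: Topology = Topology.LINEAR

    @property
    def n_d(self) -> int:
        return sum(1 for m in self.monomers if m.isomery is IsomeryState.D)

    def __len__(self) -> int:
        return len(self.monomers)


def parse_monomer_string(text: str) -> MonomerString:
    """Parse Norine-style notation; ``parse(render(x)) == x``."""
    s = text.strip()
    if not s:
        raise ArchitectureError("empty monomer string")
    topology = Topology.LINEAR
    if s.startswith("[") and s.endswith("]"):
        topology = Topology.CYCLIC
        s = s[1:-1]
    monomers = []
    for fld in s.split(","):
        name = fld.strip()
        if not name:
            raise ArchitectureError(f"empty monomer name in {text!r}")
        iso = IsomeryState.L
        if name.startswith("D-"):
            iso = IsomeryState.D
            name = name[2:]
            if not name:
                raise ArchitectureError(f"bare 'D-' prefix in {text!r}")
        monomers.append(Monomer(name, iso))
    return MonomerString(monomers, topology)


def render_monomer_string(ms: MonomerString) -> str:
    body = ",".join(
        ("D-" if m.isomery is IsomeryState.D else "") + m.name for m in ms.monomers
    )
    return f"[{body}]" if ms.topology is Topology.CYCLIC else body
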