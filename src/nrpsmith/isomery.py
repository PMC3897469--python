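"""Monomer isomery inference, topology hints, rendering and catalog matching.

Given a subtype-classified assembly and per-module monomer candidates
(from external A-domain specificity predictors), the isomery rules decide
which peptide positions carry D-monomers:

* **R1** — an E-domain inside module *i* epimerizes the monomer of
  position *i* (D).  E-domains are normally followed by a DCL leading the
  next module; its absence is flagged but does not retract the call.
* **R2** — a dual C/E domain leading module *i* epimerizes the monomer on
  the *preceding* T-domain, position *i-1* (D).
* **R3** — a DCL leading module *i+1* without an E in module *i* implies
  an expected-but-unexplained D at position *i* (D_UNCONFIRMED, e.g. a
  trans-acting racemase supply).
* **R4** — an Ala candidate with an alanine racemase (Alr) gene present
  may be loaded directly as D-Ala (D_UNCONFIRMED).

D is absorbing: later rules never downgrade D, and D beats D_UNCONFIRMED.
Genus rules add topology hints: a Pseudomonas assembly with a C-starter,
a terminal Te-Te tandem and no E-domain is a suspected cyclic lipopeptide
(CLP); a fungal assembly ending in Ct predicts a cyclic peptide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .archmodel import (
    Assembly,
    DomainToken,
    IsomeryState,
    Monomer,
    MonomerString,
    Organism,
    Topology,
    parse_monomer_string,
)


class IsomeryError(ValueError):
    """Raised for empty inputs where the contract requires content."""


_RULE_TEXT = {
    "R1": "E-domain in this module epimerizes its monomer",
    "R2": "dual C/E in the next module epimerizes the preceding T-domain monomer",
    "R3": "DCL in the next module without upstream E: D expected, source unverified",
    "ALR": "The D-Ala is provided by Alanine racemase",
}

_PRIORITY = {
    IsomeryState.L: 0,
    IsomeryState.UNKNOWN: 0,
    IsomeryState.D_UNCONFIRMED: 1,
    IsomeryState.D: 2,
}


@dataclass
class MonomerCall:
    """Isomery verdict for one peptide position."""

    position: int  # 1-based peptide index
    candidates: list[str]
    isomery: IsomeryState = IsomeryState.L
    rationale: str = "default: no epimerization evidence, called L"
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.candidates:
            raise IsomeryError(f"empty candidate list at position {self.position}")


@dataclass
class PeptidePrediction:
    """Ordered monomer calls plus assembly-level structure hints."""

    calls: list[MonomerCall]
    topology: Topology = Topology.UNKNOWN
    lipo_prefix: bool = False
    clp_suspected: bool = False
    chromophore_offset: bool = False
    provenance: str = ""
    warnings: list[str] = field(default_factory=list)


def _set_isomery(call: MonomerCall, state: IsomeryState, rule: str) -> None:
    if _PRIORITY[state] > _PRIORITY[call.isomery]:
        call.isomery = state
        call.rationale = f"{rule}: {_RULE_TEXT[rule]}"


def infer_isomery(
    assembly: Assembly,
    monomer_predictions: list[list[str]] | None = None,
    racemase_present: bool = False,
) -> list[MonomerCall]:
    """Apply the epimerization rules R1-R4 module by module.

    ``monomer_predictions`` holds one candidate list per module (defaults
    to ``["X"]`` everywhere when absent).  The rules only emit warnings,
    never errors; a dual C/E leading module 1 has no preceding monomer to
    act on and is recorded as the CE_NO_PRECEDING warning.
    """
    n = assembly.n_modules
    if monomer_predictions is None:
        monomer_predictions = [["X"]] * n
    if len(monomer_predictions) != n:
        raise IsomeryError(
            f"{len(monomer_predictions)} candidate lists for {n} modules"
        )
    calls = [
        MonomerCall(position=i + 1, candidates=list(c) or ["X"])
        for i, c in enumerate(monomer_predictions)
    ]
    mods = assembly.modules
    for i, mod in enumerate(mods):
        if mod.has_E:  # R1
            _set_isomery(calls[i], IsomeryState.D, "R1")
            if i + 1 < n and mods[i + 1].leading_c is not DomainToken.DCL:
                calls[i].warnings.append("E_WITHOUT_DCL")
        if mod.leading_c is DomainToken.CE:  # R2
            if i == 0:
                calls[i].warnings.append("CE_NO_PRECEDING")
            else:
                _set_isomery(calls[i - 1], IsomeryState.D, "R2")
        if mod.leading_c is DomainToken.DCL and i > 0 and not mods[i - 1].has_E:  # R3
            _set_isomery(calls[i - 1], IsomeryState.D_UNCONFIRMED, "R3")
        if racemase_present and "Ala" in calls[i].candidates:  # R4
            _set_isomery(calls[i], IsomeryState.D_UNCONFIRMED, "ALR")
    return calls


def predict_topology(assembly: Assembly) -> tuple[Topology, bool, bool]:
    """Structure hints from assembly architecture and organism.

    Returns ``(topology, lipo_prefix, clp_suspected)``: a C-starter leading
    module 1 marks a lipopeptide prefix; the Pseudomonas CLP pattern is
    C-starter + terminal Te-Te tandem + no E-domain; a fungal assembly
    whose last domain is Ct predicts a cyclic peptide.
    """
    mods = assembly.modules
    lipo = bool(mods) and mods[0].leading_c is DomainToken.CSTARTER
    tokens = assembly.all_tokens
    te_tandem = len(tokens) >= 2 and tokens[-1] is DomainToken.TE and tokens[-2] is DomainToken.TE
    no_e = not any(m.has_E for m in mods)
    clp = (
        assembly.organism_hint is Organism.PSEUDOMONAS
        and lipo
        and te_tandem
        and no_e
    )
    topology = Topology.UNKNOWN
    if tokens and tokens[-1] is DomainToken.CT and assembly.organism_hint is Organism.FUNGUS:
        topology = Topology.CYCLIC
    return topology, lipo, clp


def predict_structure(
    assembly: Assembly,
    monomer_predictions: list[list[str]] | None = None,
    racemase_present: bool = False,
    chromophore_candidates: list[str] | None = None,
) -> PeptidePrediction:
    """Full structure prediction: isomery calls plus topology hints.

    ``chromophore_candidates`` (e.g. ``["ChrP", "ChrI", "ChrD"]`` for a
    pyoverdin) prepends a position-1 chromophore call and shifts every
    module's reported position by one; the flag is set explicitly by the
    caller, never inferred from sequence.
    """
    calls = infer_isomery(assembly, monomer_predictions, racemase_present)
    topology, lipo, clp = predict_topology(assembly)
    warnings = [w for c in calls for w in c.warnings]
    chromophore_offset = chromophore_candidates is not None
    if chromophore_offset:
        for c in calls:
            c.position += 1
        chrom = MonomerCall(
            position=1,
            candidates=list(chromophore_candidates),
            isomery=IsomeryState.L,
            rationale="chromophore moiety preceding the peptide side chain",
        )
        calls = [chrom] + calls
    return PeptidePrediction(
        calls=calls,
        topology=topology,
        lipo_prefix=lipo,
        clp_suspected=clp,
        chromophore_offset=chromophore_offset,
        warnings=warnings,
    )


def render_norine(prediction: PeptidePrediction) -> str:
    """Render a prediction in Norine-style notation.

    Positions are comma-separated in order; D-monomers carry the ``D-``
    prefix; alternative candidates are grouped as ``{a|b|c}`` in input
    order; a cyclic topology wraps the whole string in brackets.
    D_UNCONFIRMED positions render without the prefix (the D state is
    expected but unverified).
    """
    parts = []
    for call in prediction.calls:
        body = (
            call.candidates[0]
            if len(call.candidates) == 1
            else "{" + "|".join(call.candidates) + "}"
        )
        if call.isomery is IsomeryState.D:
            body = "D-" + body
        parts.append(body)
    text = ",".join(parts)
    return f"[{text}]" if prediction.topology is Topology.CYCLIC else text


def prediction_to_monomer_string(prediction: PeptidePrediction) -> MonomerString:
    """Collapse an alternative-free prediction to a MonomerString."""
    monomers = []
    for call in prediction.calls:
        if len(call.candidates) != 1:
            raise IsomeryError(
                f"position {call.position} has alternatives; cannot collapse"
            )
        iso = (
            IsomeryState.D
            if call.isomery is IsomeryState.D
            else IsomeryState.L
            if call.isomery is IsomeryState.L
            else IsomeryState.UNKNOWN
        )
        monomers.append(Monomer(call.candidates[0], iso))
    topo = (
        prediction.topology
        if prediction.topology in (Topology.LINEAR, Topology.CYCLIC)
        else Topology.LINEAR
    )
    return MonomerString(monomers, topo)


# --- catalog matching ------------------------------------------------------


@dataclass(frozen=True)
class CatalogEntry:
    """One known peptide: an identifier and its monomer string."""

    id: str
    monomers: MonomerString


def read_catalog(path) -> list[CatalogEntry]:
    """Read a two-column TSV catalog: ``id<TAB>monomer_string``."""
    entries = []
    seen = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            ident, text = line.split("\t", 1)
            if ident in seen:
                raise IsomeryError(f"duplicate catalog id {ident}")
            seen.add(ident)
            entries.append(CatalogEntry(ident, parse_monomer_string(text)))
    return entries


def _isomery_compatible(
    call_state: IsomeryState, entry_state: IsomeryState, strict: bool
) -> bool:
    if strict:
        return call_state is entry_state
    if call_state in (IsomeryState.UNKNOWN, IsomeryState.D_UNCONFIRMED):
        return True
    return call_state is entry_state


@dataclass(frozen=True)
class CatalogMatch:
    entry: CatalogEntry
    n_matched: int
    full: bool


def match_catalog(
    prediction: PeptidePrediction,
    catalog: list[CatalogEntry],
    min_positional_matches: int | None = None,
    strict_isomery: bool = False,
) -> list[CatalogMatch]:
    """Rank catalog peptides by positional agreement with a prediction.

    A position matches when any predicted candidate (with a compatible
    isomery) equals the catalog monomer at that position; UNKNOWN and
    D_UNCONFIRMED isomery are compatible with both L and D entries unless
    ``strict_isomery``.  Entries of a different length never match.  The
    default threshold requires a full match; lowering
    ``min_positional_matches`` relaxes it.  Results are ranked by match
    count, ties by id.
    """
    if not catalog:
        raise IsomeryError("empty catalog")
    npos = len(prediction.calls)
    threshold = npos if min_positional_matches is None else min_positional_matches
    out = []
    for entry in catalog:
        if len(entry.monomers) != npos:
            continue
        matched = 0
        for call, mono in zip(prediction.calls, entry.monomers.monomers):
            if mono.name in call.candidates and _isomery_compatible(
                call.isomery, mono.isomery, strict_isomery
            ):
                matched += 1
        if matched >= threshold:
            out.append(CatalogMatch(entry, matched, matched == npos))
    out.sort(key=lambda m: (-m.n_matched, m.entry.id))
    return out


# --- D-monomer statistics --------------------------------------------------


@dataclass(frozen=True)
class DStatistics:
    """Census of D-monomers over a peptide collection."""

    n_peptides: int
    n_monomers: int
    n_D: int
    n_with_ge1_D: int
    n_with_gt1_D: int

    @property
    def freq_D(self) -> float:
        return self.n_D / self.n_monomers

    @classmethod
    def from_counts(
        cls,
        n_peptides: int,
        n_monomers: int,
        n_D: int,
        n_with_ge1_D: int = 0,
        n_with_gt1_D: int = 0,
    ) -> "DStatistics":
        return cls(n_peptides, n_monomers, n_D, n_with_ge1_D, n_with_gt1_D)


def d_statistics(peptides: list[MonomerString]) -> DStatistics:
    """Exact D-monomer counts and frequency over a peptide list."""
    if not peptides:
        raise IsomeryError("d_statistics requires at least one peptide")
    n_monomers = sum(len(p) for p in peptides)
    n_d = sum(p.n_d for p in peptides)
    ge1 = sum(1 for p in peptides if p.n_d >= 1)
    gt1 = sum(1 for p in peptides if p.n_d > 1)
    return DStatistics(len(peptides), n_monomers, n_d, ge1, gt1)
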