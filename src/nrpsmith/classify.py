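"""Condensation/epimerization domain subtype classification.

Two independent routes assign a subtype to every C/E-superfamily domain:

* **Context rules** use only the domain neighborhood on the protein: a
  C-domain with fewer than 50 residues upstream is a C-starter; in a
  tandem of two C-cores with no intervening A-domain the first is an
  epimerization (E) domain and the second a DCL; everything else is LCL.
* **Signature matching** scans the domain's Down-Seq region with each
  subtype's ordered WL windows and takes the best-scoring model, provided
  it clears an absolute threshold and beats the runner-up by a margin.

``reconcile`` merges the two: a confident signature call wins, context
fills in when the signature is uninformative, and a disagreement between
two confident calls is flagged rather than hidden.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .archmodel import C_TYPES, DomainAnnotation, DomainToken
from .logos import SignatureModel


class ClassifyError(ValueError):
    """Raised for empty model sets or mismatched domain references."""


class CallMethod(enum.Enum):
    CONTEXT = "context"
    SIGNATURE = "signature"
    RECONCILED = "reconciled"


#: Upstream length (aa) below which a protein's first C-domain is a C-starter.
CSTARTER_UPSTREAM_MAX = 50

#: Maximum gap (aa) between two C-core hits for the tandem C-C rule.  The
#: Down-Seq of the first core (an E domain's differentiating region,
#: 150-171 aa) always lies between consecutive cores, so the cap sits at
#: the spacer hard-band upper bound rather than below it.
TANDEM_MAX_GAP = 210


@dataclass
class SubtypeCall:
    """Classification verdict for one C/E-superfamily domain."""

    protein_id: str
    interval: tuple[int, int]
    subtype: DomainToken | None  # None = UNKNOWN
    method: CallMethod
    scores: dict[DomainToken, float] = field(default_factory=dict)
    margin: float = 0.0
    conflict: bool = False
    flags: list[str] = field(default_factory=list)
    rationale: str = ""

    @property
    def is_unknown(self) -> bool:
        return self.subtype is None


def classify_by_context(
    annotations: list[DomainAnnotation],
    cstarter_upstream_max: int = CSTARTER_UPSTREAM_MAX,
    tandem_max_gap: int = TANDEM_MAX_GAP,
) -> list[SubtypeCall]:
    """Assign subtypes to generic C-domains from their protein neighborhood.

    Rules, in order of precedence per domain:

    1. the first C-domain of a protein with upstream length below
       ``cstarter_upstream_max`` is a C-starter;
    2. in a tandem of two C-cores with no intervening A-domain (gap at
       most ``tandem_max_gap``), the first is E and the second DCL;
    3. every remaining C-domain is LCL.

    Already-subtyped annotations pass through unchanged (their label is
    trusted); only generic ``C?`` rows are classified.  The rules are total
    and deterministic, and calls within a protein depend only on that
    protein's annotations.
    """
    calls: list[SubtypeCall] = []
    by_protein: dict[str, list[DomainAnnotation]] = {}
    for ann in annotations:
        by_protein.setdefault(ann.protein_id, []).append(ann)

    for protein_id, rows in by_protein.items():
        rows = sorted(rows, key=lambda r: r.start)
        c_rows = [r for r in rows if r.kind in C_TYPES]
        assigned: dict[int, tuple[DomainToken, str]] = {}

        # rule 1: C-starter by short upstream (first C of the protein)
        if c_rows:
            first = c_rows[0]
            upstream_rows = [r for r in rows if r.end <= first.start]
            if not upstream_rows and first.start < cstarter_upstream_max:
                assigned[id(first)] = (
                    DomainToken.CSTARTER,
                    f"upstream {first.start} aa < {cstarter_upstream_max}",
                )

        # rule 2: tandem C-C with no intervening A -> (E, DCL)
        i = 0
        while i < len(c_rows) - 1:
            a, b = c_rows[i], c_rows[i + 1]
            if id(a) in assigned or id(b) in assigned:
                i += 1
                continue
            gap = b.start - a.end
            intervening_a = any(
                r.kind is DomainToken.A and a.end <= r.start < b.start for r in rows
            )
            if gap <= tandem_max_gap and not intervening_a:
                assigned[id(a)] = (DomainToken.E, "first of tandem C-C")
                assigned[id(b)] = (DomainToken.DCL, "second of tandem C-C")
                i += 2
            else:
                i += 1

        for r in c_rows:
            if r.kind is not DomainToken.C_UNK:
                calls.append(
                    SubtypeCall(
                        protein_id,
                        (r.start, r.end),
                        r.kind,
                        CallMethod.CONTEXT,
                        rationale="annotated subtype trusted as given",
                    )
                )
                continue
            subtype, why = assigned.get(id(r), (DomainToken.LCL, "remaining C -> LCL"))
            calls.append(
                SubtypeCall(protein_id, (r.start, r.end), subtype, CallMethod.CONTEXT, rationale=why)
            )
    return calls


def classify_by_signature(
    downseq_sequence: str,
    models: dict[DomainToken, SignatureModel],
    threshold_frac: float = 0.6,
    min_margin: float = 3.0,
    protein_id: str = "",
    interval: tuple[int, int] = (0, 0),
) -> SubtypeCall:
    """Classify a Down-Seq by its best-matching subtype signature model.

    The combined score for a model is the total of its ordered WL window
    scores at their optimal constrained placement.  The winner must reach
    ``threshold_frac`` of its own self-consensus score and beat the
    runner-up by ``min_margin`` bits; otherwise the verdict is UNKNOWN.
    Models whose windows do not fit in a short Down-Seq are skipped with a
    flag (UNKNOWN only results if no model fits or none qualifies).
    """
    if len(models) < 2:
        raise ClassifyError("signature classification requires at least two models")
    scores: dict[DomainToken, float] = {}
    flags: list[str] = []
    for subtype, model in models.items():
        if len(downseq_sequence) < model.min_sequence_length:
            flags.append(f"TOO_SHORT_FOR_{subtype.name}")
            continue
        _, total = model.scan(downseq_sequence)
        scores[subtype] = total

    if not scores:
        return SubtypeCall(
            protein_id, interval, None, CallMethod.SIGNATURE,
            scores={}, flags=flags + ["TOO_SHORT_FOR_ALL"],
            rationale="Down-Seq shorter than every model",
        )

    ranked = sorted(scores.items(), key=lambda kv: -kv[1])
    best_subtype, best_score = ranked[0]
    margin = best_score - ranked[1][1] if len(ranked) > 1 else float("inf")
    threshold = threshold_frac * models[best_subtype].consensus_score()
    if best_score >= threshold and margin >= min_margin:
        subtype = best_subtype
        why = (
            f"best model {best_subtype} at {best_score:.1f} bits "
            f">= threshold {threshold:.1f}, margin {margin:.1f}"
        )
    else:
        subtype = None
        why = (
            f"best model {best_subtype} at {best_score:.1f} bits "
            f"(threshold {threshold:.1f}, margin {margin:.1f}) -> UNKNOWN"
        )
    return SubtypeCall(
        protein_id, interval, subtype, CallMethod.SIGNATURE,
        scores=scores, margin=max(margin, 0.0) if margin != float("inf") else 0.0,
        flags=flags, rationale=why,
    )


def reconcile(context_call: SubtypeCall, signature_call: SubtypeCall) -> SubtypeCall:
    """Merge a context call and a signature call for the same domain.

    A non-UNKNOWN signature call wins; context fills in when the signature
    is UNKNOWN; when both are confident and disagree the signature verdict
    is kept with the conflict flag set (both rationales retained).
    Reconciliation is idempotent: reconciling a call with itself, or
    re-reconciling an output, changes nothing.
    """
    if (
        context_call.protein_id != signature_call.protein_id
        or context_call.interval != signature_call.interval
    ):
        raise ClassifyError(
            f"mismatched domain refs: {context_call.protein_id}{context_call.interval}"
            f" vs {signature_call.protein_id}{signature_call.interval}"
        )
    conflict = (
        not context_call.is_unknown
        and not signature_call.is_unknown
        and context_call.subtype is not signature_call.subtype
    )
    subtype = (
        signature_call.subtype
        if not signature_call.is_unknown
        else context_call.subtype
    )
    return SubtypeCall(
        protein_id=context_call.protein_id,
        interval=context_call.interval,
        subtype=subtype,
        method=CallMethod.RECONCILED,
        scores=dict(signature_call.scores),
        margin=signature_call.margin,
        conflict=conflict or context_call.conflict or signature_call.conflict,
        flags=sorted(set(context_call.flags) | set(signature_call.flags)),
        rationale=f"context: {context_call.rationale} | signature: {signature_call.rationale}",
    )
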