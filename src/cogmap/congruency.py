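"""Additive-expectation rules for bimodal stimulation and congruency scoring.

If bimodal responses were simply the sum of the two unimodal drives, the
bimodal label of a neuron would follow from its IV and VCN labels.  Of the
nine possible (IV, VCN) label pairs, seven yield a clear additive
expectation — matching signs summate, and a response paired with no
response keeps its sign.  The two opposite-sign pairs (excited/inhibited)
are inconclusive, because the additive outcome depends on the relative
weight of excitation and inhibition; these are "no rule" cases.

A neuron whose observed bimodal label matches its expectation is congruent;
one with an expectation that differs is incongruent.  Verdicts are computed
on labels rather than firing-rate changes — a conservative choice, since
frequency responses are rarely linear.
"""

from __future__ import annotations

from dataclasses import dataclass

from .response_analysis import Condition, ResponseLabel, ResponseMap

__all__ = [
    "NO_RULE",
    "EXPECTATION_TABLE",
    "CongruencyReport",
    "expected_bimodal",
    "score_congruency",
]


class _NoRule:
    """Sentinel for inconclusive (opposite-sign) unimodal label pairs."""

    def __repr__(self) -> str:
        return "NO_RULE"


NO_RULE = _NoRule()

_EX, _INH, _NR = (
    ResponseLabel.EXCITED,
    ResponseLabel.INHIBITED,
    ResponseLabel.NONRESPONSIVE,
)

#: (IV label, VCN label) -> expected bimodal label; 7 conclusive, 2 NO_RULE.
EXPECTATION_TABLE: dict[tuple[ResponseLabel, ResponseLabel], ResponseLabel | _NoRule] = {
    (_EX, _EX): _EX,
    (_INH, _INH): _INH,
    (_NR, _NR): _NR,
    (_EX, _NR): _EX,
    (_NR, _EX): _EX,
    (_INH, _NR): _INH,
    (_NR, _INH): _INH,
    (_EX, _INH): NO_RULE,
    (_INH, _EX): NO_RULE,
}


def expected_bimodal(
    iv: ResponseLabel, vcn: ResponseLabel
) -> ResponseLabel | _NoRule:
    """Additive expectation for the bimodal label, or ``NO_RULE``."""
    iv, vcn = ResponseLabel(iv), ResponseLabel(vcn)
    return EXPECTATION_TABLE[(iv, vcn)]


@dataclass
class CongruencyReport:
    """Per-neuron verdicts and their population proportions (percent)."""

    verdicts: dict[str, str]  # neuron -> congruent | incongruent | no_rule
    expected: dict[str, ResponseLabel | _NoRule]

    @property
    def n_neurons(self) -> int:
        return len(self.verdicts)

    @property
    def proportions(self) -> dict[str, float]:
        total = self.n_neurons
        if total == 0:
            raise ValueError("empty report")
        return {
            v: 100.0 * sum(1 for x in self.verdicts.values() if x == v) / total
            for v in ("congruent", "incongruent", "no_rule")
        }


def score_congruency(
    response_map: ResponseMap,
    conditions: tuple[Condition, Condition, Condition] = ("IV", "VCN", "bimodal"),
) -> CongruencyReport:
    """Compare observed bimodal labels against additive expectations.

    A Boolean comparison per neuron: congruent when the observed bimodal
    label equals the expectation, incongruent when an expectation exists
    and differs, no_rule when the unimodal pair is inconclusive.
    """
    iv_c, vcn_c, bi_c = conditions
    verdicts: dict[str, str] = {}
    expected: dict[str, ResponseLabel | _NoRule] = {}
    for neuron in response_map.neurons:
        try:
            iv = response_map.label(neuron, iv_c)
            vcn = response_map.label(neuron, vcn_c)
            observed = response_map.label(neuron, bi_c)
        except KeyError as exc:
            raise ValueError(
                f"neuron {neuron!r} is missing a label for one of {conditions}"
            ) from exc
        exp = expected_bimodal(iv, vcn)
        expected[neuron] = exp
        if exp is NO_RULE:
            verdicts[neuron] = "no_rule"
        else:
            verdicts[neuron] = "congruent" if observed == exp else "incongruent"
    return CongruencyReport(verdicts=verdicts, expected=expected)
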