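"""Default 10-20 channel layout, bipolar chain and hemisphere pairing.

The shipped cap is a standard 32-electrode 10-20 arrangement.  The default
bipolar derivation is a longitudinal ("double banana"-style) chain traversal
producing exactly 31 derived channels: two lateral chains, two parasagittal
chains and a midline chain.  Hemisphere pairing maps each left-chain bipolar
channel to its mirror-image right-chain channel (midline excluded), which is
what the symmetry and connectivity features consume.
"""

from __future__ import annotations

__all__ = [
    "CAP_32_LABELS",
    "DEFAULT_BIPOLAR_PAIRS",
    "DEFAULT_HEMISPHERE_PAIRS",
    "bipolar_label",
]

CAP_32_LABELS: list[str] = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8",
    "PO9", "O1", "Oz", "O2", "PO10",
]

_LEFT_LATERAL = ["Fp1", "F7", "FC5", "T7", "TP9", "CP5", "P7", "PO9", "O1"]
_RIGHT_LATERAL = ["Fp2", "F8", "FC6", "T8", "TP10", "CP6", "P8", "PO10", "O2"]
_LEFT_PARA = ["Fp1", "F3", "FC1", "C3", "CP1", "P3", "O1"]
_RIGHT_PARA = ["Fp2", "F4", "FC2", "C4", "CP2", "P4", "O2"]
_MIDLINE = ["Fz", "Cz", "Pz", "Oz"]


def _chain(labels: list[str]) -> list[tuple[str, str]]:
    return [(labels[i], labels[i + 1]) for i in range(len(labels) - 1)]


# 8 + 8 + 6 + 6 + 3 = 31 bipolar channels from the 32-electrode cap.
DEFAULT_BIPOLAR_PAIRS: list[tuple[str, str]] = (
    _chain(_LEFT_LATERAL)
    + _chain(_RIGHT_LATERAL)
    + _chain(_LEFT_PARA)
    + _chain(_RIGHT_PARA)
    + _chain(_MIDLINE)
)


def bipolar_label(anode: str, cathode: str) -> str:
    return f"{anode}-{cathode}"


def _pairing(left: list[tuple[str, str]], right: list[tuple[str, str]]):
    return [
        (bipolar_label(*a), bipolar_label(*b)) for a, b in zip(left, right)
    ]


# 14 mirror-image (left, right) bipolar channel pairs; midline chain excluded.
DEFAULT_HEMISPHERE_PAIRS: list[tuple[str, str]] = _pairing(
    _chain(_LEFT_LATERAL), _chain(_RIGHT_LATERAL)
) + _pairing(_chain(_LEFT_PARA), _chain(_RIGHT_PARA))
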