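"""Antibody panel and channel-role bookkeeping.

The study panel measures microglial/glial identity markers and
phospho-signaling markers alongside the machinery channels every CyTOF run
carries: six palladium barcode channels (3-of-6 combinatorial sample
barcoding), the EQ four-element calibration-bead channels (Ce/Eu/Ho/Lu),
an iridium DNA intercalator for viability/cell discrimination, and the
instrument's event-length and center parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import ChannelInfo

__all__ = [
    "IDENTITY_MARKERS",
    "SIGNALING_MARKERS",
    "BARCODE_CHANNELS",
    "BEAD_CHANNELS",
    "INTERCALATOR_CHANNEL",
    "INSTRUMENT_CHANNELS",
    "ROUND2_EXCLUDED",
    "PanelDefinition",
    "default_panel",
]

#: identity-round clustering markers (microglia/astrocyte/other discrimination)
IDENTITY_MARKERS: tuple[str, ...] = (
    "Olig2", "CD11b", "Fibronectin", "GFAP", "CD68", "F480", "CD45",
    "Ly6C", "Sox2", "CD40", "Galectin1", "Cx3CR1", "CD86",
)

#: phospho-/signaling markers named in the study narrative
SIGNALING_MARKERS: tuple[str, ...] = (
    "pp38", "pERK", "pRSK", "pCREB", "pS6", "pSTAT1", "pSTAT3",
    "pNFkB", "pSrc", "pAkt", "pcJun", "pgH2AX", "bCatenin", "Ki67",
    "CleavedCaspase3",
)

#: the six palladium barcode channels of the 6-choose-3 scheme
BARCODE_CHANNELS: tuple[str, ...] = ("Pd102", "Pd104", "Pd105", "Pd106", "Pd108", "Pd110")

#: EQ four-element calibration bead channels (cerium, europium, holmium, lutetium)
BEAD_CHANNELS: tuple[str, ...] = ("Ce140", "Eu151", "Eu153", "Ho165", "Lu175")

INTERCALATOR_CHANNEL = "Ir191_DNA"

INSTRUMENT_CHANNELS: tuple[str, ...] = ("Event_length", "Center")

#: identity markers dropped from the second (signaling-state) clustering round
ROUND2_EXCLUDED: tuple[str, ...] = ("CD11b", "CD45", "GFAP", "Olig2")

# plausible isotope assignments for the antibody channels; the exact
# conjugation plan is not part of any computation, only channel metadata
_METALS = {
    "Olig2": "113In", "CD11b": "115In", "Fibronectin": "141Pr", "GFAP": "143Nd",
    "CD68": "144Nd", "F480": "146Nd", "CD45": "147Sm", "Ly6C": "148Nd",
    "Sox2": "150Nd", "CD40": "152Sm", "Galectin1": "154Sm", "Cx3CR1": "158Gd",
    "CD86": "160Gd",
    "pp38": "156Gd", "pERK": "167Er", "pRSK": "161Dy", "pCREB": "159Tb",
    "pS6": "172Yb", "pSTAT1": "162Dy", "pSTAT3": "164Dy", "pNFkB": "166Er",
    "pSrc": "168Er", "pAkt": "170Er", "pcJun": "173Yb", "pgH2AX": "174Yb",
    "bCatenin": "176Yb", "Ki67": "169Tm", "CleavedCaspase3": "142Nd",
}


@dataclass
class PanelDefinition:
    """Ordered channel list with role assignments.

    Invariant: every channel carries exactly one role; channel names are
    unique.  Convenience accessors expose the per-role channel groups the
    pipeline stages need.
    """

    channels: list[ChannelInfo] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError("panel channel names must be unique")

    def names_by_role(self, *roles: str) -> list[str]:
        return [c.name for c in self.channels if c.role in roles]

    @property
    def identity_markers(self) -> list[str]:
        return self.names_by_role("identity")

    @property
    def signaling_markers(self) -> list[str]:
        return self.names_by_role("signaling")

    @property
    def markers(self) -> list[str]:
        return self.names_by_role("identity", "signaling")

    @property
    def barcode_channels(self) -> list[str]:
        return self.names_by_role("barcode")

    @property
    def bead_channels(self) -> list[str]:
        return self.names_by_role("bead")

    @property
    def intercalator(self) -> str:
        names = self.names_by_role("intercalator")
        if not names:
            raise ValueError("panel declares no intercalator channel")
        return names[0]

    @property
    def round2_markers(self) -> list[str]:
        """All markers except the identity anchors excluded from round-2 clustering."""
        return [m for m in self.markers if m not in ROUND2_EXCLUDED]


def default_panel() -> PanelDefinition:
    """The study's default panel.

    Identity markers are the thirteen used for the identity clustering
    round; signaling markers are the phospho-/state markers the study
    tracks over the stimulation time course.  Machinery channels: 6
    palladium barcodes, the Ce/Eu/Ho/Lu calibration-bead channels, an Ir191
    DNA intercalator, and the instrument's event length and center.
    """
    channels: list[ChannelInfo] = []
    for m in IDENTITY_MARKERS:
        channels.append(ChannelInfo(m, marker=m, metal=_METALS[m], role="identity"))
    for m in SIGNALING_MARKERS:
        channels.append(ChannelInfo(m, marker=m, metal=_METALS[m], role="signaling"))
    for b in BARCODE_CHANNELS:
        channels.append(ChannelInfo(b, metal=b[2:] + "Pd", role="barcode"))
    for b in BEAD_CHANNELS:
        metal = b[2:] + b[:2]
        channels.append(ChannelInfo(b, metal=metal, role="bead"))
    channels.append(ChannelInfo(INTERCALATOR_CHANNEL, metal="191Ir", role="intercalator"))
    for c in INSTRUMENT_CHANNELS:
        channels.append(ChannelInfo(c, role="instrument"))
    return PanelDefinition(channels)
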