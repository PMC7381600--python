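"""Per-volume branch-frequency statistics.

Branch frequency is reported as events per 10 serial sarcomeres, pooled
over all retained tracks in a volume.  Split-type frequency pools splits
and merges (static images cannot distinguish them); transfer-type
frequency pools transfers and trades.  The transfer share is the
percentage of all branch events that are myofilament transfers or
trades.  Percent branched is the fraction of retained myofibril tracks
containing at least one branch event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .tracking import MyofibrilTrack

__all__ = [
    "VolumeMetrics",
    "branch_frequency",
    "percent_branched",
    "transfer_share",
    "volume_summary",
]

SPLIT_TYPES = ("split", "merge")
TRANSFER_TYPES = ("transfer", "trade")


@dataclass
class VolumeMetrics:
    """Summary statistics for one muscle volume."""

    volume_id: str
    group: str
    n_tracks: int
    n_sarcomeres: int
    branch_freq_per10: float
    split_freq_per10: float
    transfer_freq_per10: float
    pct_branched: float
    transfer_share_pct: float | None
    mean_track_len: float
    n_events_tracked: int
    n_events_volume: int
    suppressed_events: int = 0
    ambiguous_events: int = 0

    def __post_init__(self):
        tol = 1e-9
        if abs(self.branch_freq_per10 - (self.split_freq_per10 + self.transfer_freq_per10)) > tol:
            raise ValueError("branch frequency must equal the sum of type frequencies")
        if not 0 <= self.pct_branched <= 100:
            raise ValueError("pct_branched must lie in [0, 100]")
        if self.transfer_share_pct is not None and not 0 <= self.transfer_share_pct <= 100:
            raise ValueError("transfer_share_pct must lie in [0, 100]")
        if self.n_sarcomeres < self.n_tracks:
            raise ValueError("each track traverses at least one sarcomere")


def _totals(tracks: list[MyofibrilTrack]) -> tuple[int, int]:
    n_events = sum(t.n_events for t in tracks)
    n_sarc = sum(t.sarcomeres_traversed for t in tracks)
    return n_events, n_sarc


def branch_frequency(tracks: list[MyofibrilTrack], types: tuple[str, ...] | None = None) -> float:
    """Branch events per 10 serial sarcomeres across retained tracks."""
    if not tracks:
        raise ValueError("branch frequency requires at least one retained track")
    _, n_sarc = _totals(tracks)
    if n_sarc == 0:
        raise ValueError("tracks traverse zero sarcomeres")
    if types is None:
        n_events = sum(t.n_events for t in tracks)
    else:
        n_events = sum(1 for t in tracks for _, ty in t.events if ty in types)
    return 10.0 * n_events / n_sarc


def percent_branched(tracks: list[MyofibrilTrack]) -> float:
    """Percentage of tracks containing at least one branch event."""
    if not tracks:
        raise ValueError("percent branched requires at least one retained track")
    return 100.0 * sum(t.branched for t in tracks) / len(tracks)


def transfer_share(events) -> float | None:
    """Transfers + trades as a percentage of all branch events.

    ``events`` is a volume-level event list (each physical event once).
    With zero events the share is undefined and ``None`` is returned.
    """
    typed = [e for e in events if e.type != "ambiguous"]
    if not typed:
        return None
    n_tr = sum(1 for e in typed if e.type in TRANSFER_TYPES)
    return 100.0 * n_tr / len(typed)


def volume_summary(
    tracks: list[MyofibrilTrack],
    events,
    volume_id: str = "volume-0",
    group: str = "ungrouped",
    suppressed_events: int = 0,
) -> VolumeMetrics:
    """All per-volume metrics from retained tracks and classified events.

    Track-level tallies (frequencies, percent branched) count events as
    encountered along tracks; the transfer share uses the deduplicated
    volume-level event list.
    """
    if not tracks:
        raise ValueError("volume summary requires at least one retained track")
    n_events, n_sarc = _totals(tracks)
    if n_sarc == 0:
        raise ValueError("tracks traverse zero sarcomeres")
    split_f = branch_frequency(tracks, SPLIT_TYPES)
    transfer_f = branch_frequency(tracks, TRANSFER_TYPES)
    return VolumeMetrics(
        volume_id=volume_id,
        group=group,
        n_tracks=len(tracks),
        n_sarcomeres=n_sarc,
        branch_freq_per10=split_f + transfer_f,
        split_freq_per10=split_f,
        transfer_freq_per10=transfer_f,
        pct_branched=percent_branched(tracks),
        transfer_share_pct=transfer_share(events),
        mean_track_len=n_sarc / len(tracks),
        n_events_tracked=n_events,
        n_events_volume=sum(1 for e in events if e.type != "ambiguous"),
        suppressed_events=suppressed_events,
        ambiguous_events=sum(1 for e in events if e.type == "ambiguous"),
    )
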