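"""Analytic dipole volume-conduction model and electrode lead fields.

A single current dipole in an infinite homogeneous conductor stands in for
full volume-conduction modelling of the torso and head. The potential of a
dipole with moment p at the origin, observed at displacement r, is

    phi = p . r / (4 pi sigma |r|^3)

With positions in mm (converted to m internally), moments in mA.m and
sigma in S/m, phi comes out directly in mV. Bipolar channels are described
by lead vectors: ell(channel) = g(pos+) - g(pos-), where g is the point
lead function, so the channel trace is ell . p(t). This preserves the
qualitative physics relevant here — attenuation ordering with distance
(neck > ear > scalp, cross-ear > single-ear) and the near-common
projection plane that makes head channels correlate highly with Lead I —
without tissue-resolved geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, SingularityError
from .heartvec import HeartVector

__all__ = [
    "ElectrodeLayout",
    "LeadField",
    "default_layout",
    "dipole_potential",
    "point_lead",
    "lead_field_from_layout",
    "simulate_channel_rhythm",
]

_MM = 1e-3  # mm -> m


@dataclass
class ElectrodeLayout:
    """Named electrode positions (mm, body frame) and bipolar channel pairs.

    The frame puts the dipole at ``dipole_pos``; +x is towards the left
    arm, +y anterior, +z towards the head.
    """

    positions: dict[str, np.ndarray]
    channels: dict[str, tuple[str, str]]  # name -> (positive, negative) terminal
    spacing_mm: float = 25.0
    dipole_pos: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.positions = {k: np.asarray(v, dtype=float) for k, v in self.positions.items()}
        self.dipole_pos = np.asarray(self.dipole_pos, dtype=float)

    def validate_channels(self) -> None:
        for ch, (pos, neg) in self.channels.items():
            for term in (pos, neg):
                if term not in self.positions:
                    raise ConfigError(f"channel {ch!r}: electrode {term!r} not in layout")


def default_layout(spacing_mm: float = 25.0) -> ElectrodeLayout:
    """Desk-scale default geometry.

    The dipole sits at the origin; the ear cluster is ~350 mm above and
    ~100 mm posterior of it, wrists span the body laterally. Within the
    left scalp/ear/neck column all electrodes share one lateral and
    anterior coordinate (the channels are vertically aligned), scalp
    electrodes sit at helix + L/2 and helix + 3L/2 and neck electrodes at
    concha - L/2 and concha - 3L/2, with L the helix-concha separation.
    Coordinates are declared fixtures of the synthetic study, not
    anatomical reconstructions.
    """
    L = spacing_mm
    concha_z, ear_x, ear_y = 340.0, 70.0, -100.0
    helix_z = concha_z + L
    pos = {
        "left_volar_wrist": (450.0, 0.0, -200.0),
        "right_volar_wrist": (-450.0, 0.0, -200.0),
        "left_concha": (ear_x, ear_y, concha_z),
        "left_helix": (ear_x, ear_y, helix_z),
        "lower_scalp": (ear_x, ear_y, helix_z + L / 2),
        "upper_scalp": (ear_x, ear_y, helix_z + 3 * L / 2),
        "upper_neck": (ear_x, ear_y, concha_z - L / 2),
        "lower_neck": (ear_x, ear_y, concha_z - 3 * L / 2),
        "right_concha": (-ear_x, ear_y, concha_z),
        "right_helix": (-ear_x, ear_y, helix_z),
    }
    channels = {
        "wrist": ("left_volar_wrist", "right_volar_wrist"),
        "scalp": ("lower_scalp", "upper_scalp"),
        "ear": ("left_concha", "left_helix"),
        "neck": ("lower_neck", "upper_neck"),
        "left_ear": ("left_concha", "left_helix"),
        "right_ear": ("right_helix", "right_concha"),
        "cross_ear": ("left_helix", "right_concha"),
    }
    return ElectrodeLayout(positions={k: np.array(v) for k, v in pos.items()},
                           channels=channels, spacing_mm=L)


def dipole_potential(p, r_dip, r_obs, sigma: float) -> float:
    """Potential (mV) of a current dipole in an infinite homogeneous medium.

    Parameters: moment ``p`` in mA.m, positions in mm, ``sigma`` in S/m.
    Raises :class:`SingularityError` within 1 mm of the source.
    """
    if sigma <= 0:
        raise ConfigError("sigma must be positive")
    r = (np.asarray(r_obs, dtype=float) - np.asarray(r_dip, dtype=float)) * _MM
    dist = np.linalg.norm(r)
    if dist <= 1.0 * _MM:
        raise SingularityError("observation point within 1 mm of the dipole")
    return float(np.dot(np.asarray(p, dtype=float), r) / (4.0 * np.pi * sigma * dist**3))


def point_lead(r_obs, r_dip, sigma: float) -> np.ndarray:
    """Point lead function g (mV per mA.m per moment component): phi = p . g."""
    if sigma <= 0:
        raise ConfigError("sigma must be positive")
    r = (np.asarray(r_obs, dtype=float) - np.asarray(r_dip, dtype=float)) * _MM
    dist = np.linalg.norm(r)
    if dist <= 1.0 * _MM:
        raise SingularityError("observation point within 1 mm of the dipole")
    return r / (4.0 * np.pi * sigma * dist**3)


@dataclass
class LeadField:
    """Per-channel lead vectors (mV per mA.m) for a fixed dipole position."""

    vectors: dict[str, np.ndarray]
    sigma: float
    dipole_pos: np.ndarray

    def scaled(self, gains: dict[str, float]) -> "LeadField":
        """A copy with per-channel gain multipliers (unlisted channels kept)."""
        vecs = {ch: v * gains.get(ch, 1.0) for ch, v in self.vectors.items()}
        return LeadField(vectors=vecs, sigma=self.sigma, dipole_pos=self.dipole_pos.copy())


def lead_field_from_layout(layout: ElectrodeLayout, sigma: float = 0.2) -> LeadField:
    """Build the lead field from a layout by reciprocity.

    ell(channel) = g(pos+) - g(pos-); swapping terminals negates ell, and
    coincident terminals give the zero vector.
    """
    layout.validate_channels()
    vectors = {}
    for ch, (pos, neg) in layout.channels.items():
        g_pos = point_lead(layout.positions[pos], layout.dipole_pos, sigma)
        g_neg = point_lead(layout.positions[neg], layout.dipole_pos, sigma)
        vectors[ch] = g_pos - g_neg
    return LeadField(vectors=vectors, sigma=sigma, dipole_pos=layout.dipole_pos.copy())


def simulate_channel_rhythm(hv: HeartVector, lf: LeadField, channel: str) -> np.ndarray:
    """Noiseless simulated cardiac rhythm (mV) of one channel on the cycle axis."""
    if channel not in lf.vectors:
        raise ConfigError(f"unknown channel {channel!r}; have {sorted(lf.vectors)}")
    return lf.vectors[channel] @ hv.p
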