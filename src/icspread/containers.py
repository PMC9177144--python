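"""Data containers and on-disk format for multichannel IC recordings.

A recording is a trials x channels x samples voltage tensor together with
its sampling rate, probe geometry, and the stimulus protocol that produced
it.  Channel index 0 is the ventral-most recording site and the index
increases toward dorsal; along the mouse IC tonotopic axis this means
characteristic frequency *decreases* with channel index.

On disk a recording is an HDF5 file holding the tensor (dataset ``data``
with attributes ``fs``, ``channel_pitch_um``, ``channel_order`` and a JSON
``metadata`` attribute) plus a human-readable JSON sidecar
(``<stem>.protocol.json``) describing the stimulus protocol.  Trials are
stored level-major: trial ``i`` belongs to level ``i // repeats``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

MODALITIES = ("acoustic", "electric", "magnetic")

#: native amplitude unit per stimulation modality
NATIVE_UNITS = {"acoustic": "dB SPL", "electric": "mA", "magnetic": "V"}

#: dB axis label per modality (amplitude convention, 20*log10)
DB_UNITS = {"acoustic": "dB SPL", "electric": "dB mA", "magnetic": "dB V"}


class ContainerFormatError(ValueError):
    """A container file is missing a required dataset or attribute."""


class ValidationError(ValueError):
    """A container or protocol violates a structural invariant."""


def to_db(levels, modality: str) -> np.ndarray:
    """Convert native stimulus amplitudes to the modality's dB axis.

    Acoustic levels are already in dB SPL and pass through unchanged.
    Electric currents (mA) and magnetic drive voltages (V) use the
    amplitude convention 20*log10(x / 1 unit), i.e. dB mA and dB V.
    """
    levels = np.asarray(levels, dtype=float)
    if modality == "acoustic":
        return levels
    if modality in ("electric", "magnetic"):
        if np.any(levels <= 0):
            raise ValidationError(
                f"{modality} levels must be positive to convert to dB"
            )
        return 20.0 * np.log10(levels)
    raise ValidationError(f"unknown modality {modality!r}")


def from_db(levels_db, modality: str) -> np.ndarray:
    """Inverse of :func:`to_db`."""
    levels_db = np.asarray(levels_db, dtype=float)
    if modality == "acoustic":
        return levels_db
    if modality in ("electric", "magnetic"):
        return 10.0 ** (levels_db / 20.0)
    raise ValidationError(f"unknown modality {modality!r}")


@dataclass
class StimulusProtocol:
    """Stimulus schedule attached to a recording.

    Parameters
    ----------
    modality:
        One of ``acoustic``, ``electric``, ``magnetic``.
    levels:
        Strictly increasing stimulus amplitudes in native units
        (dB SPL, mA, or V respectively).
    repeats:
        Trials per level (the study convention is a minimum of 39).
    onset_s:
        Stimulus onset time within each trial epoch, seconds.
    frequency_khz:
        Tone frequency; present iff modality is acoustic.
    pulse_rate_hz:
        Stimulus repetition rate (one trial epoch per pulse).
    """

    modality: str
    levels: np.ndarray
    repeats: int = 39
    onset_s: float = 0.005
    frequency_khz: float | None = None
    pulse_rate_hz: float = 25.0

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValidationError(f"unknown modality {self.modality!r}")
        self.levels = np.asarray(self.levels, dtype=float)
        if self.levels.ndim != 1 or self.levels.size < 1:
            raise ValidationError("levels must be a non-empty 1-D sequence")
        if np.any(np.diff(self.levels) <= 0):
            raise ValidationError("levels must be strictly increasing")
        if int(self.repeats) < 1:
            raise ValidationError("repeats must be >= 1")
        self.repeats = int(self.repeats)
        if self.onset_s < 0:
            raise ValidationError("onset_s must be >= 0")
        if (self.modality == "acoustic") != (self.frequency_khz is not None):
            raise ValidationError(
                "frequency_khz must be given for acoustic stimulation "
                "and omitted otherwise"
            )
        if self.frequency_khz is not None and self.frequency_khz <= 0:
            raise ValidationError("frequency_khz must be positive")

    @property
    def n_levels(self) -> int:
        return int(self.levels.size)

    @property
    def levels_db(self) -> np.ndarray:
        """Levels on the modality's dB axis (see :func:`to_db`)."""
        return to_db(self.levels, self.modality)

    def to_dict(self) -> dict:
        d = {
            "modality": self.modality,
            "levels": [float(x) for x in self.levels],
            "repeats": self.repeats,
            "onset_s": float(self.onset_s),
            "pulse_rate_hz": float(self.pulse_rate_hz),
        }
        if self.frequency_khz is not None:
            d["frequency_khz"] = float(self.frequency_khz)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        return cls(
            modality=d["modality"],
            levels=np.asarray(d["levels"], dtype=float),
            repeats=int(d.get("repeats", 39)),
            onset_s=float(d.get("onset_s", 0.005)),
            frequency_khz=d.get("frequency_khz"),
            pulse_rate_hz=float(d.get("pulse_rate_hz", 25.0)),
        )


@dataclass
class RecordingContainer:
    """Trials x channels x samples voltage tensor with acquisition metadata."""

    data: np.ndarray
    fs: float
    channel_pitch_um: float
    protocol: StimulusProtocol | None = None
    channel_order: str = "ventral_to_dorsal"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValidationError(
                "data must be 3-D (trials x channels x samples), got "
                f"{self.data.ndim}-D"
            )
        trials, channels, _ = self.data.shape
        if trials < 1:
            raise ValidationError("need at least 1 trial")
        if channels < 2:
            raise ValidationError("need at least 2 channels")
        if not self.fs > 0:
            raise ValidationError("fs must be > 0")
        if not self.channel_pitch_um > 0:
            raise ValidationError("channel_pitch_um must be > 0")
        if self.protocol is not None:
            expected = self.protocol.n_levels * self.protocol.repeats
            if trials != expected:
                raise ValidationError(
                    f"{trials} trials inconsistent with protocol "
                    f"({self.protocol.n_levels} levels x "
                    f"{self.protocol.repeats} repeats = {expected})"
                )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def trials_by_level(self) -> np.ndarray:
        """Reshape to (levels, repeats, channels, samples); needs a protocol."""
        if self.protocol is None:
            raise ValidationError("container has no attached protocol")
        p = self.protocol
        return self.data.reshape(
            p.n_levels, p.repeats, self.n_channels, self.n_samples
        )


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".protocol.json")


def write_container(
    rec: RecordingContainer, path, overwrite: bool = False
) -> Path:
    """Write a recording to HDF5 plus its JSON protocol sidecar.

    Refuses to clobber an existing file unless ``overwrite`` is set.
    """
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(
            f"{path} exists; pass overwrite=True to replace it"
        )
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        f.attrs["fs"] = float(rec.fs)
        f.attrs["channel_pitch_um"] = float(rec.channel_pitch_um)
        f.attrs["channel_order"] = rec.channel_order
        f.attrs["metadata"] = json.dumps(rec.metadata, sort_keys=True)
    if rec.protocol is not None:
        _sidecar_path(path).write_text(
            json.dumps(rec.protocol.to_dict(), indent=2, sort_keys=True)
        )
    return path


def read_container(path) -> RecordingContainer:
    """Read a recording written by :func:`write_container`.

    Raises :class:`ContainerFormatError` naming the first missing dataset
    or attribute, and :class:`ValidationError` on invariant violations.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        if "data" not in f:
            raise ContainerFormatError("missing dataset 'data'")
        for attr in ("fs", "channel_pitch_um"):
            if attr not in f.attrs:
                raise ContainerFormatError(f"missing attribute '{attr}'")
        data = f["data"][...]
        fs = float(f.attrs["fs"])
        pitch = float(f.attrs["channel_pitch_um"])
        order = str(f.attrs.get("channel_order", "ventral_to_dorsal"))
        metadata = json.loads(f.attrs.get("metadata", "{}"))
    protocol = None
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        protocol = StimulusProtocol.from_dict(json.loads(sidecar.read_text()))
    return RecordingContainer(
        data=data,
        fs=fs,
        channel_pitch_um=pitch,
        protocol=protocol,
        channel_order=order,
        metadata=metadata,
    )
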