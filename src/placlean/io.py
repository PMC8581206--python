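"""Channel-file input/output: delimited text and (read-only) EDF.

Text dialect: UTF-8, "#"-prefixed ``key=value`` header lines (``fs_hz`` is
required, ``label`` optional), then one sample per line with "." as the
decimal separator.  Diff-friendly and parseable from any language.

EDF (European Data Format) reading is delegated to mne and is optional at
runtime: if mne is unavailable, :func:`read_edf_channel` fails with a clear
message rather than at import time.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import numpy as np

from .signal_model import SampledSignal

__all__ = ["read_channel_text", "write_channel_text", "read_edf_channel"]

_HEADER_KEY = "fs_hz"


def read_channel_text(path: Union[str, Path]) -> SampledSignal:
    """Parse a delimited-text channel file into a :class:`SampledSignal`.

    Raises ``ValueError`` with the offending line number for a missing or
    invalid ``fs_hz`` header, non-numeric sample rows, or fewer than two
    samples.
    """
    path = Path(path)
    fs: Optional[float] = None
    samples: list[float] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    if key.strip() == _HEADER_KEY:
                        try:
                            fs = float(value.strip())
                        except ValueError:
                            raise ValueError(
                                f"{path}:{lineno}: invalid {_HEADER_KEY} "
                                f"value {value.strip()!r}"
                            ) from None
                continue
            if fs is None:
                raise ValueError(
                    f"{path}:{lineno}: sample data before the required "
                    f"'# {_HEADER_KEY}=<rate>' header line"
                )
            try:
                samples.append(float(line))
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric sample {line!r}"
                ) from None
    if fs is None:
        raise ValueError(
            f"{path}: missing required header line '# {_HEADER_KEY}=<rate>'"
        )
    if len(samples) < 2:
        raise ValueError(
            f"{path}: found {len(samples)} samples; at least 2 are required"
        )
    return SampledSignal(np.array(samples), fs)


def write_channel_text(
    signal: SampledSignal, path: Union[str, Path], label: Optional[str] = None
) -> None:
    """Write a signal in the text dialect (header first, one sample per line)."""
    if isinstance(path, str) and path == "":
        raise ValueError("empty output path")
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# {_HEADER_KEY}={float(signal.sampling_rate_hz)!r}\n")
        if label is not None:
            fh.write(f"# label={label}\n")
        for value in signal.samples:
            fh.write(f"{float(value)!r}\n")


def read_edf_channel(path: Union[str, Path], channel_label: str) -> SampledSignal:
    """Read one channel of an EDF recording as a :class:`SampledSignal`.

    Requires mne; an unknown channel label raises with the list of available
    labels. The sampling rate is always taken from the EDF header.
    """
    try:
        from mne.io import read_raw_edf
    except ImportError as exc:  # pragma: no cover - mne present in normal installs
        raise RuntimeError(
            "EDF reading requires the optional 'mne' package, which is not "
            "installed; convert the channel to the text dialect instead"
        ) from exc
    raw = read_raw_edf(str(path), preload=True, verbose="error")
    if channel_label not in raw.ch_names:
        raise ValueError(
            f"channel {channel_label!r} not in {path}; available channels: "
            f"{', '.join(raw.ch_names)}"
        )
    data = raw.get_data(picks=[channel_label])[0]
    return SampledSignal(np.asarray(data, dtype=float), float(raw.info["sfreq"]))
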