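"""Shared fixtures: small simulation configs and a minimal FCS writer.

The FCS writer exists only to build write-then-read fixtures for the
reader; it emits the smallest valid FCS 3.0 file (one TEXT segment,
little-endian float32 list-mode DATA).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from splitfp.simulate.flow import TransfectionSimConfig
from splitfp.simulate.imaging import ImagingSimConfig


def write_minimal_fcs(
    path: Path,
    data: pd.DataFrame,
    ranges: dict[str, float] | None = None,
) -> None:
    """Write a little-endian float32 FCS 3.0 file with the frame's columns."""
    names = list(data.columns)
    values = data.to_numpy(dtype="<f4")
    n_tot, n_par = values.shape

    kv = {
        "$MODE": "L",
        "$DATATYPE": "F",
        "$BYTEORD": "1,2,3,4",
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
        "$NEXTDATA": "0",
    }
    for i, name in enumerate(names, start=1):
        kv[f"$P{i}N"] = name
        kv[f"$P{i}B"] = "32"
        kv[f"$P{i}E"] = "0,0"
        if ranges and name in ranges:
            kv[f"$P{i}R"] = str(ranges[name])

    delim = "/"
    text = delim + delim.join(f"{k}{delim}{v}" for k, v in kv.items()) + delim
    text_bytes = text.encode("ascii")

    header_len = 58
    text_start = header_len
    text_end = text_start + len(text_bytes) - 1
    data_start = text_end + 1
    data_end = data_start + values.nbytes - 1

    header = (
        b"FCS3.0    "
        + f"{text_start:>8d}".encode()
        + f"{text_end:>8d}".encode()
        + f"{data_start:>8d}".encode()
        + f"{data_end:>8d}".encode()
        + f"{0:>8d}".encode()  # analysis start
        + f"{0:>8d}".encode()  # analysis end
    )
    assert len(header) == header_len
    path.write_bytes(header + text_bytes + values.tobytes())


@pytest.fixture
def fcs_writer():
    return write_minimal_fcs


@pytest.fixture
def quiet_flow_config() -> TransfectionSimConfig:
    """Small, noise-light transfection sim for fast pipeline tests."""
    return TransfectionSimConfig(
        n_events=4000,
        kd=100.0,
        autofluor_green_mean=1e-6,
        autofluor_green_sd=5e-7,
        autofluor_blue_mean=1e-6,
        autofluor_blue_sd=5e-7,
        rho=0.95,
        transfected_fraction=1.0,
        doublet_fraction=0.0,
        seed=1,
    )


@pytest.fixture
def small_imaging_config() -> ImagingSimConfig:
    """Small field for fast imaging tests."""
    return ImagingSimConfig(
        field_shape=(160, 160),
        n_cells=10,
        cell_radius_px_mean=10.0,
        cell_radius_px_sd=1.5,
        seed=3,
    )
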