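"""Built-in fixture generators: default morphology, strain fields, CA params.

The default airway morphology is a symmetric Weibel-type table for
generations 0-7 (trachea radius 9 mm down to 1.15 mm bronchioles) shipped
as a versioned CSV inside the package; wall-layer thicknesses are fixed
fractions of the lumen radius (epithelium 5 %, connective tissue 10 %,
smooth muscle 15 %). Everything is overridable through the simulation
config.
"""

from __future__ import annotations

from dataclasses import asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cell_ca import CAParams

FIXTURE_KINDS = ("morphology", "strain_field", "ca_params")


def default_morphology() -> pd.DataFrame:
    """Per-generation geometry table: gn, radius_m, length_m, t_epi_m,
    t_conn_m, t_asm_m."""
    with resources.files("ventilam.data").joinpath("morphology_weibel.csv").open() as f:
        return pd.read_csv(f)


def load_morphology(path: str | Path | None) -> pd.DataFrame:
    """Morphology from a user CSV, or the built-in default when path is None."""
    if path is None:
        return default_morphology()
    df = pd.read_csv(path)
    required = {"gn", "radius_m", "length_m", "t_epi_m", "t_conn_m", "t_asm_m"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"morphology file {path} is missing columns {sorted(missing)}")
    return df


def generate_fixtures(kind: str, seed: int = 0, outdir: str | Path = ".",
                      level: float = 0.0, shape: tuple[int, int] = (100, 100)) -> Path:
    """Write a deterministic default fixture file and return its path.

    ``morphology``: the Weibel-type CSV. ``strain_field``: a uniform
    per-site strain CSV at ``level``. ``ca_params``: the default CAParams
    as YAML. The same seed always produces identical bytes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if kind == "morphology":
        path = outdir / "morphology.csv"
        default_morphology().to_csv(path, index=False)
    elif kind == "strain_field":
        path = outdir / "strain_field.csv"
        field = np.full(shape, float(level))
        pd.DataFrame(field).to_csv(path, index=False, header=False)
    elif kind == "ca_params":
        path = outdir / "ca_params.yaml"
        params = asdict(CAParams(seed=seed))
        path.write_text(yaml.safe_dump(params, sort_keys=True))
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    return path
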