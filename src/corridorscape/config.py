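"""YAML run-configuration loading.

One structured YAML file can configure all stages; CLI flags override its
values.  Recognized top-level keys (all optional) and their fields mirror
the corresponding dataclasses:

.. code-block:: yaml

    landscape:            # synthetic.LandscapeConfig fields
      nrows: 200
      ncols: 300
      cell_size_m: 30.0
    pesticide:            # synthetic.PesticideConfig fields
      interannual_cv: 0.3
      years: [2014, 2015, 2016]
      chemicals:
        - name: spinosad
          ld50_range_ug_per_bee: [0.0029, 0.0029]
          base_rate_lbs_per_acre: 0.0047
    run:                  # pipeline.RunConfig fields
      point_spacing_m: 500.0
      n_iterations: 5
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .pipeline import RunConfig
from .synthetic import ChemicalSpec, LandscapeConfig, PesticideConfig


def load_config(
    path: str | Path | None,
) -> tuple[LandscapeConfig, PesticideConfig, RunConfig]:
    """Parse a YAML config file into the three stage configurations."""
    doc = {}
    if path is not None:
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}

    land = dict(doc.get("landscape") or {})
    for key in ("origin", "parcel_side_range", "crops"):
        if key in land and isinstance(land[key], list):
            land[key] = tuple(
                tuple(v) if isinstance(v, list) else v for v in land[key]
            ) if key == "crops" else tuple(land[key])
    lcfg = LandscapeConfig(**land)

    pest = dict(doc.get("pesticide") or {})
    if "chemicals" in pest:
        pest["chemicals"] = tuple(
            ChemicalSpec(
                name=c["name"],
                ld50_range_ug_per_bee=tuple(c["ld50_range_ug_per_bee"]),
                base_rate_lbs_per_acre=float(c["base_rate_lbs_per_acre"]),
            )
            for c in pest["chemicals"]
        )
    if "years" in pest:
        pest["years"] = tuple(pest["years"])
    pcfg = PesticideConfig(**pest)

    rcfg = RunConfig(**(doc.get("run") or {}))
    return lcfg, pcfg, rcfg
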