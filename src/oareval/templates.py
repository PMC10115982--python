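"""YAML (de)serialization of plan-quality scoring templates.

A template file is a mapping with a ``template_id`` and a list of
``objectives``::

    template_id: clinic-hn-2024
    objectives:
      - structure: SpinalCord
        statistic: D0.03cc
        direction: "<="
        threshold: 45.0
        points: 2.0
        zero_threshold: 50.0      # optional linear partial-credit ramp
      - structure: Parotid_L
        statistic: Dmean
        direction: "<="
        threshold: 26.0
        points: 1.0
        use_eval_region: true     # default
"""

from __future__ import annotations

import os
from typing import Union

import yaml

from .dosimetry import PQMObjective, PQMTemplate

PathLike = Union[str, os.PathLike]


def load_template(path: PathLike) -> PQMTemplate:
    with open(os.fspath(path)) as fh:
        doc = yaml.safe_load(fh)
    objectives = [
        PQMObjective(
            structure=str(o["structure"]),
            statistic=str(o["statistic"]),
            direction=str(o["direction"]),
            threshold=float(o["threshold"]),
            points=float(o.get("points", 1.0)),
            zero_threshold=(
                float(o["zero_threshold"]) if o.get("zero_threshold") is not None
                else None
            ),
            use_eval_region=bool(o.get("use_eval_region", True)),
        )
        for o in doc["objectives"]
    ]
    return PQMTemplate(objectives, template_id=str(doc.get("template_id", "custom")))


def dump_template(template: PQMTemplate, path: PathLike) -> None:
    doc = {
        "template_id": template.template_id,
        "objectives": [
            {
                "structure": o.structure,
                "statistic": o.statistic,
                "direction": o.direction,
                "threshold": o.threshold,
                "points": o.points,
                "zero_threshold": o.zero_threshold,
                "use_eval_region": o.use_eval_region,
            }
            for o in template.objectives
        ],
    }
    with open(os.fspath(path), "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
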