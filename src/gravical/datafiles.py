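"""Access to the small reference datasets shipped with the package.

These are plain-text CSVs: the screening reference table (per-solvent probe
statistics of the five predefined liquid classes), the two adsorption-
capacity plates and the phosphophilicity plate used for reproducibility
statistics, and the printed acceptance-criteria cells.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path


def data_path(filename: str) -> Path:
    """Filesystem path of a packaged data file."""
    ref = resources.files("gravical") / "data" / filename
    return Path(str(ref))


SCREENING_REFERENCE = "screening_reference.csv"
ADSORPTION_PLATES = "adsorption_capacity_plates.csv"
PHOSPHOPHILICITY_PLATE = "phosphophilicity_plate.csv"
ACCEPTANCE_CRITERIA = "acceptance_criteria.csv"
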