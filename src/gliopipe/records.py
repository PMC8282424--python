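"""Case-level record shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GRADES = ("II", "III", "IV")
HISTOLOGIES = ("AA", "OA", "OD", "GBM")


@dataclass
class CaseRecord:
    """One patient case: molecular profile, grade, ROI image and nuclei mask.

    Molecular encodings follow clinical shorthand: IDH and ATRX are mutant
    (MT) or wild-type (WT); 1p/19q is codeleted (CD) or non-codeleted (NC);
    MGMT promoter is methylated (ML) or unmethylated (UM).
    """

    case_id: str
    grade: str
    histology: str
    idh: str
    atrx: str
    codel_1p19q: str
    mgmt: str
    image: np.ndarray | None = None
    mask: np.ndarray | None = None
    roi_paths: list = field(default_factory=list)
    cellularity: float | None = None

    def __post_init__(self):
        if self.grade not in GRADES:
            raise ValueError(f"grade must be one of {GRADES}, got {self.grade!r}")
        if self.histology not in HISTOLOGIES:
            raise ValueError(
                f"histology must be one of {HISTOLOGIES}, got {self.histology!r}"
            )
        for name, val, allowed in (
            ("idh", self.idh, ("MT", "WT")),
            ("atrx", self.atrx, ("MT", "WT")),
            ("codel_1p19q", self.codel_1p19q, ("CD", "NC")),
            ("mgmt", self.mgmt, ("ML", "UM")),
        ):
            if val is not None and val not in allowed:
                raise ValueError(f"{name} must be in {allowed}, got {val!r}")

    @property
    def molecular_vector(self) -> np.ndarray:
        """Binary encoding: IDH MT=1, ATRX MT=1, 1p/19q CD=1, MGMT ML=1.

        Missing markers are imputed as 0 with a trailing missingness bit.
        """
        vals, missing = [], []
        for val, pos in (
            (self.idh, "MT"),
            (self.atrx, "MT"),
            (self.codel_1p19q, "CD"),
            (self.mgmt, "ML"),
        ):
            vals.append(0.0 if val is None else float(val == pos))
            missing.append(float(val is None))
        return np.array(vals + missing)
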