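"""Class label conventions shared across the pipeline.

Two labelings coexist:

* ``TissueClass`` — the four tissue classes of the final segmentation
  (lumen, stroma, nuclei, DAB), used by the phantom generator's ground
  truth and by the class-fraction report.
* ``StainClass`` — the three stain classes of the supervised DAB detector
  (hematoxylin, DAB, lumen) plus an "unlabeled" value, used in training
  masks.  Hematoxylin covers both stroma and nuclei: the counterstain
  binds unspecifically, so both appear as shades of blue.
"""

from enum import IntEnum


class TissueClass(IntEnum):
    LUMEN = 0
    STROMA = 1
    NUCLEI = 2
    DAB = 3


class StainClass(IntEnum):
    UNLABELED = 0
    HEMATOXYLIN = 1
    DAB = 2
    LUMEN = 3


#: Order of the stain classes in classifier outputs (posterior columns).
STAIN_CLASS_ORDER = (StainClass.HEMATOXYLIN, StainClass.DAB, StainClass.LUMEN)

#: Canonical order of class names in a 4-map posterior stack after ordering
#: by average grayscale intensity (darkest first) with DAB appended last.
FOUR_CLASS_NAMES = ("Nuclei", "Stroma", "Lumen", "DAB")

#: Mapping from the 3-cluster rank (ascending mean intensity) to a name.
CLUSTER_NAMES_BY_INTENSITY = ("Nuclei", "Stroma", "Lumen")
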