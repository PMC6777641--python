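"""Small bundled example datasets.

``EXAMPLE_GRID_CSV`` is a gridline-intersect phosphate dose-response
experiment (three phosphate levels, seven biological replicates each);
``EXAMPLE_TROUVELOT_CSV`` is a strigolactone-analog experiment scored with
the Trouvelot method, including technical replicates (several fragments per
biological replicate).
"""

from __future__ import annotations

import io

from .tabular_io import Dataset, read_colonization_table

EXAMPLE_GRID_CSV = """\
Samples,Replicates,Total,Hyphopodia,IntrHyphae,Arbuscule,Vesicle
Low phosphate,A,88,4,88,78,40
Low phosphate,B,95,4,95,76,35
Low phosphate,C,87,6,87,70,31
Low phosphate,D,74,5,74,62,27
Low phosphate,E,95,3,95,79,25
Low phosphate,F,93,4,93,85,41
Low phosphate,G,80,4,80,59,20
Medium phosphate,A,79,4,79,61,27
Medium phosphate,B,72,3,72,59,20
Medium phosphate,C,52,2,52,40,21
Medium phosphate,D,80,4,80,63,29
Medium phosphate,E,53,2,53,41,15
Medium phosphate,F,63,4,63,49,25
Medium phosphate,G,62,4,62,48,24
High phosphate,A,21,2,21,21,8
High phosphate,B,7,1,7,5,2
High phosphate,C,5,1,5,5,2
High phosphate,D,18,2,18,18,6
High phosphate,E,7,1,7,5,1
High phosphate,F,17,2,17,11,2
High phosphate,G,2,0,2,2,1
"""

EXAMPLE_TROUVELOT_CSV = """\
Samples,Replicates,Scoring
Control,1,3A3
Control,1,5A3
Control,1,3A3
Control,2,4A3
Control,2,2A3
Control,2,2A3
GR24 10-7M,1,3A3
GR24 10-7M,1,3A3
GR24 10-7M,1,3A3
GR24 10-7M,2,5A3
GR24 10-7M,2,5A3
GR24 10-7M,3,5A3
MP3 10-8M,1,4A3
MP3 10-8M,1,5A3
MP3 10-8M,1,4A3
MP3 10-8M,2,3A2
MP3 10-8M,2,5A3
MP3 10-8M,2,5A3
MP1 10-7M,1,3A2
MP1 10-7M,1,5A2
MP1 10-7M,1,1A2
MP1 10-7M,2,3A2
MP1 10-7M,2,2A3
MP1 10-7M,2,2A3
"""


def load_example_grid() -> Dataset:
    """The bundled grid example as a validated Dataset."""
    return read_colonization_table(io.StringIO(EXAMPLE_GRID_CSV), "grid")


def load_example_trouvelot() -> Dataset:
    """The bundled Trouvelot example as a validated Dataset."""
    return read_colonization_table(io.StringIO(EXAMPLE_TROUVELOT_CSV),
                                   "trouvelot")
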