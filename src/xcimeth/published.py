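"""Published summary tables from a sex-stratified X-chromosome 450K aging
study of Danish twin cohorts (LSADT, MADT) with LBC1921 validation.

These printed counts are inputs for recomputing the study's summary
statistics (region-by-pattern chi-squared, age-association-by-pattern
chi-squareds, replication overlap tests and rate rows) without access to
the underlying cohort data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import GENE_REGIONS

#: CpGs analysed on the X chromosome after QC (the overlap-test universe)
X_UNIVERSE = 10_096

#: gene-region x XCI-pattern frequency counts (X chromosome)
REGION_PATTERN_COUNTS = pd.DataFrame(
    [
        [471, 43, 146, 7, 123],
        [19, 3, 281, 14, 82],
        [711, 102, 225, 38, 313],
        [669, 90, 891, 33, 420],
        [433, 114, 546, 23, 388],
        [854, 122, 600, 24, 462],
        [1130, 174, 255, 10, 280],
    ],
    index=pd.Index(GENE_REGIONS, name="gene_region"),
    columns=pd.Index(["A", "B", "C", "D", "REST"], name="pattern"),
)

#: age-association (FDR > / <= 0.05) by pattern, per cohort and sex:
#: rows = (insignificant, significant), columns = patterns A..D, REST
AGE_BY_PATTERN_COUNTS = {
    ("lsadt", "female"): np.array([[3890, 463, 2269, 122, 1834],
                                   [397, 185, 675, 27, 234]]),
    ("madt", "female"): np.array([[4128, 455, 1960, 137, 1875],
                                  [159, 193, 984, 12, 193]]),
    ("lsadt", "male"): np.array([[4195, 632, 2505, 140, 1928],
                                 [92, 16, 439, 9, 140]]),
    ("madt", "male"): np.array([[3664, 536, 2305, 126, 1698],
                                [623, 112, 639, 23, 370]]),
}

#: hyper/hypo counts of age-significant X-linked CpGs per cohort and class
AGE_DIRECTION_COUNTS = {
    ("lsadt", "both"): (149, 10),
    ("lsadt", "male_only"): (434, 103),
    ("lsadt", "female_only"): (897, 462),
    ("madt", "both"): (325, 90),
    ("madt", "male_only"): (466, 886),
    ("madt", "female_only"): (887, 239),
}

#: cross-cohort replication per class: (m = LSADT count, n = MADT count,
#: k = overlap)
REPLICATION_COUNTS = {
    "both": (159, 415, 55),
    "male_only": (537, 1352, 123),
    "female_only": (1359, 1126, 293),
}

#: third-cohort validation per class: (validated, replicated)
VALIDATION_COUNTS = {
    "both": (3, 55),
    "male_only": (16, 123),
    "female_only": (24, 293),
}
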