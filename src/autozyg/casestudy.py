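"""Published summary inputs of the French Bulldog DSD case study.

The raw sequencing data of the case are not publicly deposited; the
published per-dog ROH summary statistics below (segment count NSEG and
cumulative length KB, in kb) are therefore the real-data inputs the
package can recompute derived quantities from: KBAVG, F_ROH, the breed
baseline, and the sib-mating expectation.

``BRUTUS`` is the DSD proband; ``FATHERB`` its sire; ``BUFALO`` and
``TAURO`` unrelated intact males of the same breed.
"""

from __future__ import annotations

from .inbreeding import AUTOSOME_KB_CANFAM6

#: sample -> (NSEG, total KB) from the published ROH analysis (CanFam6).
ROH_TOTALS = {
    "Brutus": (298, 681_002.0),
    "Bufalo": (153, 299_507.0),
    "FatherB": (170, 318_511.0),
    "Tauro": (154, 292_152.0),
}

PROBAND = "Brutus"
FATHER = "FatherB"
CONTROLS = ("Bufalo", "FatherB", "Tauro")

#: Karyotyping outcome: metaphase spreads with the 77,XX fusion line
#: out of spreads examined.
MOSAIC_ABNORMAL, MOSAIC_TOTAL = 18, 82

AUTOSOME_KB = AUTOSOME_KB_CANFAM6
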