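"""Shared locations and settings of the numbered analysis scripts.

The study runs on a synthetic world generated by the selfish-mother
scenario (viviparous clades occupy reproductive-season climates with lower
temperature and precipitation seasonality).  Scripts write raster data
under scratch/ (bulky, regenerable) and tables under results/.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"
WORLD_DIR = SCRATCH / "world"
OCC_CSV = WORLD_DIR / "occurrences.csv"

SEED = 7
PRESET = "smh_reproductive"
BACKGROUND_N = 5000
N_REPS = 199
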