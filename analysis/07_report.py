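"""Render the markdown report and summary figures from results/."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from sprucegs.pipeline import write_report

ROOT = Path(__file__).resolve().parents[1] / "results"
for p in write_report(ROOT):
    print(f"wrote {p}")
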