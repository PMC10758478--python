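#!/usr/bin/env python
"""Stage 4 — one-way deterministic sensitivity analysis (tornado).

Sets each uncertain parameter to its published low and high bound with all
others at base, re-runs the full model, and writes tornado tables and plots
(sorted by ICER spread) under results/dsa/ for both populations.
"""

from pathlib import Path

from psmcea import plots
from psmcea.config import default_config
from psmcea.engine import run_cea
from psmcea.sensitivity import one_way_dsa, tornado_table

OUT = Path(__file__).resolve().parents[1] / "results" / "dsa"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = default_config()
    for population in ("overall", "esr1"):
        base = run_cea(cfg, population)
        entries = one_way_dsa(cfg, population)
        tornado_table(entries).to_csv(OUT / f"tornado_{population}.csv",
                                      index=False, float_format="%.10g")
        plots.plot_tornado(entries, base.icer, OUT / f"tornado_{population}.png")
        print(f"\n== {population} (base ICER ${base.icer:,.0f}/QALY) ==")
        for e in entries[:5]:
            print(f"  {e.param:45s} spread ${e.spread:,.0f}")
    print(f"\nwrote tornado tables and plots to {OUT}")


if __name__ == "__main__":
    main()
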