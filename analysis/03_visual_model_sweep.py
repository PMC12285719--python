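"""Avian-eye view of the sweeps: double-cone luminance and tetrahedral chroma.

Scores every swept stack through the violet-sensitive tetrachromat visual
system.  Expected pattern: white hidden layers raise the luminance of
carotenoid-pigmented plumage at every optical density, and black hidden
layers raise the chroma of structurally colored plumage at every peak height.

Writes results/visual_sweep_carotenoid.csv and results/visual_sweep_structural.csv.
"""

from pathlib import Path

from plumelayers.experiments import (
    DEFAULT_D_GRID,
    DEFAULT_HPK_GRID,
    SweepConfig,
    run_visual_sweep,
)
from plumelayers.vision import build_visual_system

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    vs = build_visual_system()
    caro = run_visual_sweep(SweepConfig("carotenoid", "D", DEFAULT_D_GRID), vs)
    caro.to_csv(OUT / "visual_sweep_carotenoid.csv", index=False)
    white = caro[caro.background == "white"]
    print(
        f"carotenoid: luminance(white) > luminance(black) at "
        f"{(white.delta_luminance_vs_black > 0).mean():.0%} of {len(white)} densities"
    )

    struct = run_visual_sweep(SweepConfig("structural", "Hpk", DEFAULT_HPK_GRID), vs)
    struct.to_csv(OUT / "visual_sweep_structural.csv", index=False)
    sw = struct[struct.background == "white"]
    print(
        f"structural: chroma(black) > chroma(white) at "
        f"{(sw.delta_chroma_vs_black < 0).mean():.0%} of {len(sw)} peak heights"
    )


if __name__ == "__main__":
    main()
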