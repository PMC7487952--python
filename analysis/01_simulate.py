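"""Generate the synthetic linked claims+EHR study population.

Draws a 20,000-patient world under the default study conditions (operation
mix 10/32/58% AGB/RYGB/SG, preoperative BMI mean 46.1 sd 9.0 kg/m^2, 15%
EHR linkage, adjacent-category coding kernel with preoperative up-coding)
and writes the five analysis tables under results/world/.
"""

from pathlib import Path

from claimsbmi import GeneratorConfig, generate

OUT = Path(__file__).resolve().parent.parent / "results" / "world"

if __name__ == "__main__":
    cfg = GeneratorConfig(n_patients=20_000, seed=20240901)
    world = generate(cfg)
    world.to_csv(OUT)
    print(f"wrote {len(world.patients)} patients, {len(world.diagnoses)} "
          f"diagnosis records, {len(world.bmi)} BMI measurements -> {OUT}")
    (OUT / "generator.yaml").write_text(cfg.model_dump_json(indent=2))
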