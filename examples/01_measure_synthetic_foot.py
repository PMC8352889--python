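"""Measure one synthetic weight-bearing flatfoot.

Builds the flatfoot template (a parametric skeleton whose pose reproduces
a published flexible-flatfoot cohort), runs the full 32-measurement
pipeline on its triangle meshes, and compares a few clinically familiar
angles against the generator's closed-form ground truth.
"""

from footmetry import compute_all, default_templates, generate_foot

normal, flatfoot = default_templates()
foot, truth = generate_foot(flatfoot)
measured = compute_all(foot, method="ideal-mesh")

print(f"foot {foot.foot_id}: {len(measured.values)} measurements")
print(f"{'code':10s} {'measured':>9s} {'truth':>9s}  meaning")
rows = [
    ("RL_TAM1", "Meary angle (talus vs 1st metatarsal, lateral); negative = flatfoot"),
    ("IL_CA", "calcaneal inclination, lateral (negative = anterior end dorsal)"),
    ("I3_CA", "calcaneal pitch measured in 3D"),
    ("IT_TA", "talar internal rotation, transverse plane"),
    ("RL_CAM1", "Hibb angle; approaches 180 deg as the arch flattens"),
    ("RL_TACAM1", "Moreau-Costa-Bertani medial arch angle, lateral"),
    ("Hg_NA", "navicular height above ground, mm"),
    ("FAO_%", "foot-ankle offset, % of foot length (valgus positive)"),
]
for code, meaning in rows:
    print(f"{code:10s} {measured[code]:9.2f} {truth.expected[code]:9.2f}  {meaning}")
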