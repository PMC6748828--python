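"""Inflate one idealised meristematic cell and read off the swelling.

Builds the default 20 x 10 x 10 um box-shell wall (0.5 um thick), assigns
the baseline isotropic wall composite everywhere, pressurises the cavity to
0.8 MPa turgor and reports the maximum displacement of the outer face plus
the edge/face stress concentration ratio.
"""

from wallmech.experiments import make_scenario, run_scenario

spec = make_scenario(case_id=1, edge_factor=1.0, load_steps=16)
report = run_scenario(spec)

print(f"scenario:                     {spec.label()}")
print(f"turgor pressure:              {spec.turgor_pressure} MPa")
print(f"max outer-face displacement:  {report.max_outer_displacement:.3f} um")
print(f"edge/face von Mises ratio:    {report.edge_face_vm_ratio:.3f}")
print(f"Newton iterations:            {report.n_newton_iterations}")
print()
print("The displacement is the bulging of the outer (periclinal) wall under")
print("turgor; the stress ratio compares the mean von Mises stress in the")
print("edge bands with the mean over the faces (1 = no edge concentration).")
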