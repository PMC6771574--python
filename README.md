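# littplan

Automated stereotactic trajectory planning for laser interstitial thermal
therapy (LITT) of the mesial temporal lobe.

LITT treats mesial temporal lobe epilepsy by threading a laser fibre along a
pre-planned path from an occipito-temporal entry point to the
amygdalohippocampal complex and thermally ablating tissue around the fibre.
The plan must balance safety (an avascular corridor, no ventricular
transgression, clearance from the brainstem and sulci, a drilling angle
close to orthogonal to the skull) against efficacy (maximal ablation of the
amygdala and hippocampal head while sparing the parahippocampal gyrus).
`littplan` automates this search on a labeled brain volume: it is aimed at
researchers studying trajectory-planning strategies, and it ships a seeded
synthetic-phantom generator so the whole pipeline runs without any patient
data.

## Method

Given a parcellation (NIfTI label volume + role map) the planner:

1. **Targets.** Computes the amygdala centroid **c** and one of three target
   parameterizations: `centroid_T2` (target = **c**, inferior occipital
   gyrus entry), `expert_T3` (**c** + 3 mm anterior + 3 mm medial + 3 mm
   inferior, same entry region) and `ml_T4` (**c** + 3 mm anterior + 3 mm
   medial, temporo-occipital junction entry). Medial is resolved toward the
   mid-sagittal plane per hemisphere.
2. **Entry search.** Enumerates the entry region's outer-surface voxels and,
   for each candidate entry, applies the hard constraints: length ≤ 120 mm,
   drilling angle ≤ 30° from the skull-surface normal, no lateral-ventricle
   transgression, ≥ 3 mm from vessels and sulci, ≥ 7 mm from the brainstem.
3. **Risk score.** Places *n* = 128 equally spaced nodes on the trajectory
   and reads each node's distance *d* to the nearest vessel off a Euclidean
   distance field. Each node scores
   *r(d) = (d_max − min(d, d_max)) / (d_max − d_safe)* with
   *d_safe* = 3 mm and *d_max* = 10 mm, so *r* = 1 exactly at the safety
   margin and *r* > 1 inside it; the trajectory's score is the mean over
   nodes (fixed node count keeps long and short trajectories comparable).
4. **Ablation estimate.** Models the thermal cavity as a uniform-diameter
   capsule (default 15 mm) along the distal trajectory, pulled back as long
   as the capsule still touches the mesial ROI complex, and reports overlap
   volume and percentage of preoperative volume for the amygdala,
   hippocampus, entorhinal cortex and parahippocampal gyrus.
5. **Ranking.** Feasible candidates are ordered by ascending risk score,
   then descending amygdala + hippocampus ablation %, then ascending length.

## Worked example

```python
import littplan as lp

vol, role_map, truth = lp.generate_phantom(lp.PhantomSpec(seed=0))
scene = lp.build_scene(vol, role_map)
for method in ("centroid_T2", "expert_T3", "ml_T4"):
    best = lp.plan(scene, lp.PlanningConstraints(), lp.TargetSpec(method), k=1)[0]
    m = best.metrics
    print(f"{method}: risk {m['risk_score']:.3f}  length {m['length_mm']:.1f} mm  "
          f"angle {m['drilling_angle_deg']:.1f} deg")
```

prints

```
centroid_T2: risk 0.095  length 56.3 mm  angle 14.7 deg
expert_T3: risk 0.091  length 59.6 mm  angle 15.0 deg
ml_T4: risk 0.113  length 60.9 mm  angle 19.6 deg
```

Risk scores well below 1 mean every node of each rank-1 trajectory sits
comfortably outside the 3 mm vessel safety margin (the phantom carves a
guaranteed avascular corridor); lengths and drilling angles sit inside the
120 mm and 30° hard bounds. On this phantom the three methods trade off
coverage differently — e.g. `ml_T4` spares the parahippocampal gyrus
entirely (0 % ablation) while keeping 84 % amygdala coverage.

The same pipeline is available from the shell:

```bash
litt phantom --seed 0 --out-dir ph
litt plan --labels ph/labels.nii.gz --rolemap ph/rolemap.yaml --method ml --out-dir out
litt evaluate --labels ph/labels.nii.gz --rolemap ph/rolemap.yaml \
     --entry=-23,-55,-17 --target=-22,2,-15
litt compare --metrics out/metrics.csv --metric risk_score
```

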