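# Study configuration: receptor helix ranges with x.50 anchors (generic
# numbering is defined relative to these), targeted Asp pockets, and the
# default contact statistics planted by the synthetic pose generator.
#
# Helix ranges/anchors are chosen so that the targeted aspartates carry
# the literature residue numbers and generic labels (TAAR1 Asp68=2.50,
# Asp102=3.32, Asp284=6.61; TAAR6 Asp78=2.50, Asp112=3.32, Asp202=5.42).
design:
  models: 5
  replicates: 3
  poses_per_run: 10
ligands: [PEA, TYM, PUT, CAD, ABU]
receptors:
  TAAR1:
    chain: A
    helices:
      - {id: 1, start: 24, end: 53, anchor: 38}
      - {id: 2, start: 58, end: 87, anchor: 68}
      - {id: 3, start: 94, end: 123, anchor: 120}
      - {id: 4, start: 130, end: 159, anchor: 147}
      - {id: 5, start: 166, end: 195, anchor: 181}
      - {id: 6, start: 260, end: 289, anchor: 273}
      - {id: 7, start: 295, end: 324, anchor: 309}
    pocket_asp: {68: "2.50", 102: "3.32", 284: "6.61"}
    pockets:
      BP_1: [68, 102, 284]
      BP_2: [68, 102]
      BP_3: [102, 284]
      BP_4: [68, 284]
      BP_5: []
  TAAR6:
    chain: A
    helices:
      - {id: 1, start: 34, end: 63, anchor: 48}
      - {id: 2, start: 68, end: 97, anchor: 78}
      - {id: 3, start: 104, end: 133, anchor: 130}
      - {id: 4, start: 140, end: 169, anchor: 157}
      - {id: 5, start: 190, end: 219, anchor: 210}
      - {id: 6, start: 262, end: 291, anchor: 275}
      - {id: 7, start: 300, end: 329, anchor: 315}
    pocket_asp: {78: "2.50", 112: "3.32", 202: "5.42"}
    pockets:
      BP_1: [78, 112, 202]
      BP_2: [78, 112]
      BP_3: [112, 202]
      BP_4: [78, 202]
      BP_5: []
# Planted contact statistics.  Marginals are per-residue contact
# probabilities (by generic number), scaled per ligand; joints are
# pairwise simultaneity probabilities applied when both residues of the
# pair are in the run's pocket.  Pairs not listed have joint zero, as do
# all triplets.  The unconstrained (BP_5) control plants weak marginals
# and puts nonzero joints only in a subset of models.
contacts:
  base_marginal: {"2.50": 0.30, "3.32": 0.55, "5.42": 0.25, "6.61": 0.05}
  unconstrained_marginal: {"2.50": 0.08, "3.32": 0.18, "5.42": 0.02, "6.61": 0.02}
  ligand_factor: {PEA: 0.4, TYM: 0.8, PUT: 1.0, CAD: 1.0, ABU: 0.6}
  joints:
    TAAR1:
      PUT: {"2.50+3.32": 0.20}
      CAD: {"2.50+3.32": 0.20}
    TAAR6:
      PUT: {"2.50+3.32": 0.20, "3.32+5.42": 0.20}
      CAD: {"2.50+3.32": 0.20, "3.32+5.42": 0.20}
      TYM: {"2.50+3.32": 0.15, "3.32+5.42": 0.15}
  unconstrained_joints:
    TAAR1:
      PUT: {"2.50+3.32": {models: [1, 2, 3], q: 0.05}}
      CAD: {"2.50+3.32": {models: [1, 2], q: 0.05}}
    TAAR6:
      PUT: {"2.50+3.32": {models: [1], q: 0.05}}
      CAD: {"2.50+3.32": {models: [1], q: 0.05}}
      TYM: {"2.50+3.32": {models: [1], q: 0.05}}
scaffold:
  residues_per_helix: 30
  ring_radius: 11.0
  helix_radius: 2.3
  rise_per_residue: 1.5
  turn_per_residue_deg: 100.0
  model_jitter_sd: 0.35
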