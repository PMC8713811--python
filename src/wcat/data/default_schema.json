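{
 "version": "default-1.0",
 "frames": [
  {
   "name": "DISTAL_A1TYPE",
   "length": 88,
   "consensus": "HEVSKKFDIWDHLMLQWAKRYSVWTLRKPNYMNRIRIVKPRIKWRGGNQIMEVSTMVVIHYRGEWFAHHENPRTEGYFRMWFWYHWYI",
   "numbering_origin": 1
  },
  {
   "name": "DISTAL_A2TYPE",
   "length": 88,
   "consensus": "PPDWSVIKTDTHPALYWEWKKTGIAEPQKQREFVHVRYFYSWKFWWWIPRDQNVIEPYKFHDGFIKTKARPAVGYRKAFTEYGYDHWR",
   "numbering_origin": 1
  },
  {
   "name": "IG_C1",
   "length": 94,
   "consensus": "EGFVIMSQQEFDQFKLYDYVCMHKRNAKRLLLMNMYWYYMAGLGNIENQAVQNEIIIHGSEHHVAQWVSFFIGWDCHNNHMTVKFGMGHLHDHA",
   "numbering_origin": 1
  },
  {
   "name": "TM",
   "length": 25,
   "consensus": "LFLLIMIAIAFMIALFAVFFMVALF",
   "numbering_origin": 1
  }
 ],
 "signatures": [
  {
   "frame": "DISTAL_A1TYPE",
   "position": 30,
   "allowed_residues": "V",
   "chain_class": "I_HEAVY",
   "role": "INTERFACE_A1A2_B2M",
   "weight": 2.0
  },
  {
   "frame": "DISTAL_A1TYPE",
   "position": 30,
   "allowed_residues": "V",
   "chain_class": "WA",
   "role": "INTERFACE_A1A2_B2M",
   "weight": 2.0
  },
  {
   "frame": "DISTAL_A2TYPE",
   "position": 6,
   "allowed_residues": "Q",
   "chain_class": "I_HEAVY",
   "role": "INTERFACE_A1A2_B2M",
   "weight": 0.5
  },
  {
   "frame": "DISTAL_A2TYPE",
   "position": 6,
   "allowed_residues": "Q",
   "chain_class": "WB",
   "role": "INTERFACE_A1A2_B2M",
   "weight": 0.5
  },
  {
   "frame": "DISTAL_A2TYPE",
   "position": 32,
   "allowed_residues": "A",
   "chain_class": "I_HEAVY",
   "role": "INTERFACE_A1A2_B2M",
   "weight": 2.0
  },
  {
   "frame": "DISTAL_A2TYPE",
   "position": 32,
   "allowed_residues": "A",
   "chain_class": "WB",
   "role": "INTERFACE_A1A2_B2M",
   "weight": 2.0
  },
  {
   "frame": "DISTAL_A2TYPE",
   "position": 35,
   "allowed_residues": "G",
   "chain_class": "I_HEAVY",
   "role": "INTERFACE_A1A2_B2M",
   "weight": 2.0
  },
  {
   "frame": "DISTAL_A2TYPE",
   "position": 35,
   "allowed_residues": "G",
   "chain_class": "WB",
   "role": "INTERFACE_A1A2_B2M",
   "weight": 2.0
  },
  {
   "frame": "DISTAL_A2TYPE",
   "position": 37,
   "allowed_residues": "D",
   "chain_class": "I_HEAVY",
   "role": "INTERFACE_A1A2_B2M",
   "weight": 2.0
  },
  {
   "frame": "DISTAL_A2TYPE",
   "position": 37,
   "allowed_residues": "D",
   "chain_class": "WB",
   "role": "INTERFACE_A1A2_B2M",
   "weight": 2.0
  },
  {
   "frame": "IG_C1",
   "position": 8,
   "allowed_residues": "Y",
   "chain_class": "B2M",
   "role": "INTERFACE_A3_B2M",
   "weight": 2.0
  },
  {
   "frame": "IG_C1",
   "position": 8,
   "allowed_residues": "Y",
   "chain_class": "WA",
   "role": "INTERFACE_A3_B2M",
   "weight": 2.0
  },
  {
   "frame": "IG_C1",
   "position": 37,
   "allowed_residues": "W",
   "chain_class": "IGSF_CORE",
   "role": "CORE",
   "weight": 1.0
  },
  {
   "frame": "IG_C1",
   "position": 37,
   "allowed_residues": "L",
   "chain_class": "B2M",
   "role": "CORE",
   "weight": 1.0
  },
  {
   "frame": "IG_C1",
   "position": 37,
   "allowed_residues": "FL",
   "chain_class": "WA",
   "role": "CORE",
   "weight": 1.0
  },
  {
   "frame": "IG_C1",
   "position": 37,
   "allowed_residues": "W",
   "chain_class": "IIA",
   "role": "CORE",
   "weight": 1.0
  },
  {
   "frame": "IG_C1",
   "position": 37,
   "allowed_residues": "W",
   "chain_class": "IIB",
   "role": "CORE",
   "weight": 1.0
  },
  {
   "frame": "IG_C1",
   "position": 37,
   "allowed_residues": "W",
   "chain_class": "WB",
   "role": "CORE",
   "weight": 1.0
  },
  {
   "frame": "IG_C1",
   "position": 37,
   "allowed_residues": "W",
   "chain_class": "I_HEAVY",
   "role": "CORE",
   "weight": 1.0
  },
  {
   "frame": "IG_C1",
   "position": 55,
   "allowed_residues": "L",
   "chain_class": "B2M",
   "role": "INTERFACE_A1A2_B2M",
   "weight": 2.0
  },
  {
   "frame": "IG_C1",
   "position": 55,
   "allowed_residues": "L",
   "chain_class": "WA",
   "role": "INTERFACE_A1A2_B2M",
   "weight": 2.0
  },
  {
   "frame": "IG_C1",
   "position": 57,
   "allowed_residues": "F",
   "chain_class": "B2M",
   "role": "INTERFACE_A1A2_B2M",
   "weight": 2.0
  },
  {
   "frame": "IG_C1",
   "position": 57,
   "allowed_residues": "FY",
   "chain_class": "WA",
   "role": "INTERFACE_A1A2_B2M",
   "weight": 2.0
  },
  {
   "frame": "IG_C1",
   "position": 57,
   "allowed_residues": "P",
   "chain_class": "I_HEAVY",
   "role": "INTERFACE_A3_B2M",
   "weight": 2.0
  },
  {
   "frame": "IG_C1",
   "position": 57,
   "allowed_residues": "P",
   "chain_class": "WB",
   "role": "INTERFACE_A3_B2M",
   "weight": 2.0
  },
  {
   "frame": "IG_C1",
   "position": 61,
   "allowed_residues": "W",
   "chain_class": "B2M",
   "role": "INTERFACE_A1A2_B2M",
   "weight": 2.0
  },
  {
   "frame": "IG_C1",
   "position": 61,
   "allowed_residues": "W",
   "chain_class": "WA",
   "role": "INTERFACE_A1A2_B2M",
   "weight": 2.0
  },
  {
   "frame": "IG_C1",
   "position": 61,
   "allowed_residues": "G",
   "chain_class": "I_HEAVY",
   "role": "INTERFACE_A1A2_A3",
   "weight": 2.0
  },
  {
   "frame": "IG_C1",
   "position": 61,
   "allowed_residues": "G",
   "chain_class": "WB",
   "role": "INTERFACE_A1A2_A3",
   "weight": 2.0
  },
  {
   "frame": "IG_C1",
   "position": 61,
   "allowed_residues": "W",
   "chain_class": "IIB",
   "role": "INTERFACE_A1A2_A3",
   "weight": 2.0
  }
 ],
 "indel_regions": [
  {
   "frame": "DISTAL_A1TYPE",
   "start_column": 44,
   "end_column": 46,
   "present_in": [
    "I_HEAVY",
    "WA"
   ],
   "absent_in": [
    "IIA"
   ],
   "provisional": true
  },
  {
   "frame": "DISTAL_A2TYPE",
   "start_column": 50,
   "end_column": 53,
   "present_in": [
    "I_HEAVY",
    "WB"
   ],
   "absent_in": [
    "IIB"
   ],
   "provisional": true
  },
  {
   "frame": "DISTAL_A2TYPE",
   "start_column": 70,
   "end_column": 71,
   "present_in": [
    "I_HEAVY",
    "WB"
   ],
   "absent_in": [
    "IIB"
   ],
   "provisional": true
  }
 ],
 "tm_glycine_patterns": {
  "provisional": true,
  "patterns": {
   "WA": [
    8,
    12,
    16
   ],
   "IIA": [
    8,
    12,
    16
   ],
   "WB": [
    9,
    13,
    17
   ],
   "IIB": [
    9,
    13,
    17
   ]
  }
 },
 "invariant_cysteine_positions": [
  21,
  76
 ]
}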