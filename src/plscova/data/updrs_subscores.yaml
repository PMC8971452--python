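# MDS-UPDRS part III item -> motor subscore grouping.
# The 33 motor-exam items are partitioned into tremor, bradykinesia,
# rigidity and axial subscores; the total score is the sum of all 33.
# The partition follows the commonly used clinical grouping of the motor
# examination; it is configuration, not code — supply your own map to
# override.
tremor:
  - "3.15a"   # postural tremor, right hand
  - "3.15b"   # postural tremor, left hand
  - "3.16a"   # kinetic tremor, right hand
  - "3.16b"   # kinetic tremor, left hand
  - "3.17a"   # rest tremor amplitude, RUE
  - "3.17b"   # rest tremor amplitude, LUE
  - "3.17c"   # rest tremor amplitude, RLE
  - "3.17d"   # rest tremor amplitude, LLE
  - "3.17e"   # rest tremor amplitude, lip/jaw
  - "3.18"    # constancy of rest tremor
rigidity:
  - "3.3a"    # rigidity, neck
  - "3.3b"    # rigidity, RUE
  - "3.3c"    # rigidity, LUE
  - "3.3d"    # rigidity, RLE
  - "3.3e"    # rigidity, LLE
bradykinesia:
  - "3.2"     # facial expression
  - "3.4a"    # finger tapping, right
  - "3.4b"    # finger tapping, left
  - "3.5a"    # hand movements, right
  - "3.5b"    # hand movements, left
  - "3.6a"    # pronation-supination, right
  - "3.6b"    # pronation-supination, left
  - "3.7a"    # toe tapping, right
  - "3.7b"    # toe tapping, left
  - "3.8a"    # leg agility, right
  - "3.8b"    # leg agility, left
  - "3.14"    # global spontaneity of movement
axial:
  - "3.1"     # speech
  - "3.9"     # arising from chair
  - "3.10"    # gait
  - "3.11"    # freezing of gait
  - "3.12"    # postural stability
  - "3.13"    # posture
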