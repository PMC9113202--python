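# Import-adapter mapping for an externally deposited event table.
# Maps the deposit's column headings and label spellings onto the canonical
# schema (trial_id, component, onset_s, offset_s) so the deposited files are
# never edited by hand.  Pass to courtseq.events.read_events via
# load_import_mapping().
columns:
  trial: trial_id
  signal_type: component
  start_time: onset_s
  end_time: offset_s
labels:
  REV: rev
  Idle: idle
  legtap: leg_tap
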