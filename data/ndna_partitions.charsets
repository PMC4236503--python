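#nexus
[ Nuclear protein-coding partition scheme: 11 subsets over a 7769-column
  concatenated alignment, codon positions encoded as start-end\3 stride
  ranges. ]
begin sets;
  charset subset1 = 1-691\3, 2785-3497\3, 3500-4636\3, 5323-6194\3;
  charset subset2 = 2-691\3, 692-1405\3, 3498-4636\3;
  charset subset3 = 3-691\3, 4638-5321\3, 4639-5321\3, 6197-7024\3;
  charset subset4 = 693-1405\3, 7027-7769\3;
  charset subset5 = 694-1405\3, 6196-7024\3, 7025-7769\3;
  charset subset6 = 1406-2784\3, 1408-2784\3;
  charset subset7 = 1407-2784\3, 4637-5321\3;
  charset subset8 = 2786-3497\3, 7026-7769\3;
  charset subset9 = 2787-3497\3, 3499-4636\3;
  charset subset10 = 5322-6194\3;
  charset subset11 = 5324-6194\3, 6195-7024\3;
end;
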