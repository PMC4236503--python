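#nexus
[ Mitochondrial protein-coding partition scheme: 14 subsets over a
  10061-column concatenated alignment, codon positions encoded as
  start-end\3 stride ranges. ]
begin sets;
  charset subset1 = 1-1145\3, 1832-2008\3, 6610-7665\3, 7668-9522\3;
  charset subset2 = 2-1145\3, 2010-3562\3;
  charset subset3 = 3-1145\3, 7667-9522\3;
  charset subset4 = 1146-1831\3, 1833-2008\3, 6611-7665\3, 7666-9522\3;
  charset subset5 = 1147-1831\3, 1834-2008\3, 4255-5637\3;
  charset subset6 = 1148-1831\3, 4254-5637\3, 4256-5637\3;
  charset subset7 = 2009-3562\3;
  charset subset8 = 2011-3562\3, 3565-4253\3;
  charset subset9 = 3563-4253\3, 5638-6609\3;
  charset subset10 = 3564-4253\3, 5639-6609\3;
  charset subset11 = 5640-6609\3;
  charset subset12 = 6612-7665\3;
  charset subset13 = 9523-10061\3;
  charset subset14 = 9524-10061\3, 9525-10061\3;
end;
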