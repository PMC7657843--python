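# Named model-stack presets.
#
# Numbered modes 1-5 are this package's own small-to-large stacks for
# desk-scale work.  The named entries reproduce published command strings
# for specific dataset classes; "relative" uses reference-trained frozen
# models only, "conditional" adds target-adaptive models on top of it.
"1":
  tm: ["3:1:0:0:0.9/0:0:0"]
"2":
  tm: ["1:1:0:0:0.9/0:0:0", "4:1:1:0:0.9/0:0:0"]
"3":
  tm: ["2:1:0:0:0.9/0:0:0", "6:1:1:0:0.9/0:0:0", "10:16:1:0:0.9/0:0:0"]
"4":
  tm: ["2:1:0:0:0.9/0:0:0", "5:1:1:0:0.9/0:0:0", "9:16:1:0:0.92/0:0:0",
       "12:32:1:4:0.95/2:8:0.95"]
"5":
  tm: ["2:1:0:0:0.9/0:0:0", "5:1:1:0:0.9/0:0:0", "8:4:1:0:0.92/0:0:0",
       "11:32:1:4:0.95/2:8:0.95", "14:64:1:8:0.95/3:16:0.95"]
ds2:
  tm: ["3:1:1:1:0.70/0:0:0", "8:1:1:1:0.85/0:0:0", "13:10:0:1:0.85/0:0:0",
       "19:500:1:40:0.85/5:20:0.85"]
ds3-4:
  tm: ["3:1:1:1:0.8/0:0:0", "6:1:1:1:0.85/0:0:0", "9:1:1:1:0.85/0:0:0",
       "12:10:0:1:0.85/0:0:0", "15:200:1:10:0.85/2:1:0.85",
       "17:200:1:10:0.85/2:1:0.85", "20:500:1:40:0.85/5:20:0.85"]
virome:
  tm: ["7:1:1:1:0.8/0:0:0", "13:10:0:1:0.95/0:0:0", "19:500:1:40:0.95/5:20:0.95"]
denisova:
  tm: ["7:1:0:1:0.8/0:0:0", "13:10:0:1:0.95/0:0:0", "19:500:0:40:0.95/5:20:0.95"]
relative:
  rm: ["20:500:1:35:0.95/3:100:0.95", "13:200:1:1:0.95/0:0:0",
       "10:10:0:0:0.95/0:0:0"]
conditional:
  rm: ["20:500:1:35:0.95/3:100:0.95", "13:200:1:1:0.95/0:0:0",
       "10:10:0:0:0.95/0:0:0"]
  tm: ["4:1:0:1:0.9/0:0:0", "17:100:1:10:0.95/2:20:0.95"]
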