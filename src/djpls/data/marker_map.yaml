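# Mapping from the 47-landmark capture set to the reduced 22-marker model
# vocabulary used by this package. Landmarks not listed are not required:
# arms ride rigidly on the trunk (hands on hips) and head mass is placed
# from the trunk frame.
markers:
  LASI: {segment: pelvis, landmark: left anterior-superior iliac spine}
  RASI: {segment: pelvis, landmark: right anterior-superior iliac spine}
  LPSI: {segment: pelvis, landmark: left posterior-superior iliac spine}
  RPSI: {segment: pelvis, landmark: right posterior-superior iliac spine}
  C7:   {segment: trunk, landmark: seventh cervical vertebra}
  SJN:  {segment: trunk, landmark: suprasternal notch}
  T10:  {segment: trunk, landmark: tenth thoracic vertebra}
  XIPH: {segment: trunk, landmark: xiphoid process}
  LMEP: {segment: thigh_left,  landmark: left medial femoral epicondyle}
  LLEP: {segment: thigh_left,  landmark: left lateral femoral epicondyle}
  RMEP: {segment: thigh_right, landmark: right medial femoral epicondyle}
  RLEP: {segment: thigh_right, landmark: right lateral femoral epicondyle}
  LMM:  {segment: shank_left,  landmark: left medial malleolus}
  LLM:  {segment: shank_left,  landmark: left lateral malleolus}
  RMM:  {segment: shank_right, landmark: right medial malleolus}
  RLM:  {segment: shank_right, landmark: right lateral malleolus}
  LHEE: {segment: foot_left,  landmark: left calcaneus}
  LTOE: {segment: foot_left,  landmark: left second distal phalanx apex}
  LMT5: {segment: foot_left,  landmark: left fifth metatarsal head}
  RHEE: {segment: foot_right, landmark: right calcaneus}
  RTOE: {segment: foot_right, landmark: right second distal phalanx apex}
  RMT5: {segment: foot_right, landmark: right fifth metatarsal head}
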