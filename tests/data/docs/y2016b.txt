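Architects unveiled ambitious blueprints inside packed auditoriums. Surveyors measured muddy plots beside drainage canals. Welders joined steel beams high above busy intersections. Inspectors photographed cracked facades during routine checks. Apprentices practised careful measurements under strict supervision.
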